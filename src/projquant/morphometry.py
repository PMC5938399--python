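"""Dendritic and axonal summary metrics for single reconstructions.

Conventions: an edge belongs to the compartment of its *child* node (standard
SWC practice), so soma-internal edges are never counted and a soma->neurite
edge counts toward the neurite. Cable lengths are Euclidean edge sums in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .morphology import (
    SOMA,
    NeuronReconstruction,
    compartment_codes,
)


@dataclass(frozen=True)
class MorphometrySummary:
    """Per-neuron morphometrics: dendritic cable, stems, nodes, axonal cable."""

    neuron_id: str
    dendritic_length_mm: float
    n_stems: int
    n_branch_points: int
    axonal_length_mm: float

    def as_dict(self) -> dict:
        return asdict(self)


def _edge_mask_for(neuron: NeuronReconstruction, compartment: str) -> np.ndarray:
    edges = neuron.edges()
    if compartment == "all":
        # every edge whose child is not soma (excludes soma-internal cable)
        return neuron.types[edges[:, 1]] != SOMA
    codes = compartment_codes(compartment)
    return np.isin(neuron.types[edges[:, 1]], codes)


def cable_length(neuron: NeuronReconstruction, compartment: str = "axon") -> float:
    """Total Euclidean cable length (mm) of edges in the given compartment.

    ``compartment`` is one of ``axon``, ``dendrite`` (basal+apical pooled),
    ``basal_dendrite``, ``apical_dendrite``, ``soma`` or ``all`` (all
    non-soma cable).
    """
    mask = _edge_mask_for(neuron, compartment)
    return float(neuron.edge_lengths()[mask].sum())


def count_stems(neuron: NeuronReconstruction, compartment: str = "dendrite") -> int:
    """Number of trees of the given compartment emanating from the soma."""
    codes = compartment_codes(compartment)
    edges = neuron.edges()
    mask = (neuron.types[edges[:, 0]] == SOMA) & np.isin(
        neuron.types[edges[:, 1]], codes
    )
    return int(mask.sum())


def count_branch_points(
    neuron: NeuronReconstruction, compartment: str = "dendrite"
) -> int:
    """Number of nodes of the compartment with >= 2 children of that compartment.

    A trifurcation counts once (branch points are nodes, not child pairs).
    """
    codes = compartment_codes(compartment)
    counts = neuron.child_counts(codes)
    is_comp = np.isin(neuron.types, codes)
    return int(np.count_nonzero(is_comp & (counts >= 2)))


def summarize(neuron: NeuronReconstruction) -> MorphometrySummary:
    """Assemble the standard per-neuron summary (dendrites pooled basal+apical)."""
    return MorphometrySummary(
        neuron_id=neuron.neuron_id,
        dendritic_length_mm=cable_length(neuron, "dendrite"),
        n_stems=count_stems(neuron, "dendrite"),
        n_branch_points=count_branch_points(neuron, "dendrite"),
        axonal_length_mm=cable_length(neuron, "axon"),
    )
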