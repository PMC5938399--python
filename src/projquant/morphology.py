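"""Array-backed container for single-neuron reconstructions.

A reconstruction is a rooted tree of 3D sample points. Coordinates are stored
in millimetres in a named anatomical frame with axes

* ``ml`` — medio-lateral, midline = 0, left hemisphere negative;
* ``ap`` — anterio-posterior, positive anterior to Bregma;
* ``dv`` — depth from the pial surface, increasing ventrally.

Node compartments follow the SWC type convention (1 soma, 2 axon, 3 basal
dendrite, 4 apical dendrite); other codes are carried through untouched so
that reading and re-writing a file is lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

SOMA = 1
AXON = 2
BASAL_DENDRITE = 3
APICAL_DENDRITE = 4

ROOT_PARENT = -1

#: compartment selectors accepted by the morphometry API
COMPARTMENT_GROUPS: dict[str, tuple[int, ...]] = {
    "soma": (SOMA,),
    "axon": (AXON,),
    "dendrite": (BASAL_DENDRITE, APICAL_DENDRITE),
    "basal_dendrite": (BASAL_DENDRITE,),
    "apical_dendrite": (APICAL_DENDRITE,),
}

VALID_FRAMES = ("bregma", "injection-relative", "section-local")


class MorphologyError(ValueError):
    """Structural problem in a reconstruction (orphans, cycles, bad roots)."""


class FrameError(ValueError):
    """Operation received coordinates in an unexpected anatomical frame."""


def compartment_codes(compartment: str) -> tuple[int, ...]:
    """Map a compartment name to the SWC type codes it covers."""
    try:
        return COMPARTMENT_GROUPS[compartment]
    except KeyError:
        raise ValueError(
            f"unknown compartment {compartment!r}; "
            f"expected one of {sorted(COMPARTMENT_GROUPS)} or 'all'"
        ) from None


@dataclass
class NeuronReconstruction:
    """A neuron as parallel arrays indexed 0..n-1 in parent-before-child order.

    Parameters
    ----------
    neuron_id
        Free-form identifier, e.g. ``"AP049"``.
    ids
        Original (SWC) integer sample ids, unique.
    parent_index
        Index of each node's parent into these arrays; ``-1`` for roots.
    types
        Raw SWC structure codes per node.
    xyz
        ``(n, 3)`` float array of (ml, ap, dv) in millimetres.
    radius_um
        Per-node radius in micrometres (``nan`` where unknown).
    frame
        One of ``bregma``, ``injection-relative``, ``section-local``.
    strict
        When True (default) enforce the single-tree invariants; fragments
        produced by sectioning set this to False and may hold a forest.
    """

    neuron_id: str
    ids: np.ndarray
    parent_index: np.ndarray
    types: np.ndarray
    xyz: np.ndarray
    radius_um: np.ndarray | None = None
    frame: str = "bregma"
    provenance: dict = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.parent_index = np.asarray(self.parent_index, dtype=np.int64)
        self.types = np.asarray(self.types, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.radius_um is None:
            self.radius_um = np.full(len(self.ids), np.nan)
        else:
            self.radius_um = np.asarray(self.radius_um, dtype=np.float64)
        self.validate()

    # ------------------------------------------------------------------ #
    @property
    def n_nodes(self) -> int:
        return len(self.ids)

    @property
    def root_indices(self) -> np.ndarray:
        return np.flatnonzero(self.parent_index == ROOT_PARENT)

    @property
    def soma_location(self) -> np.ndarray:
        """Coordinates of the root node (mm)."""
        roots = self.root_indices
        if len(roots) == 0:
            raise MorphologyError(f"{self.neuron_id}: no root node")
        return self.xyz[roots[0]]

    def edges(self) -> np.ndarray:
        """``(m, 2)`` array of (parent_index, child_index) pairs."""
        child = np.flatnonzero(self.parent_index != ROOT_PARENT)
        return np.column_stack([self.parent_index[child], child])

    def child_counts(self, codes: Sequence[int] | None = None) -> np.ndarray:
        """Number of children per node, optionally restricted to child types."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        child = np.flatnonzero(self.parent_index != ROOT_PARENT)
        if codes is not None:
            child = child[np.isin(self.types[child], codes)]
        np.add.at(counts, self.parent_index[child], 1)
        return counts

    def validate(self) -> None:
        n = self.n_nodes
        if len({len(self.ids), len(self.parent_index), len(self.types), n}) != 1:
            raise MorphologyError(f"{self.neuron_id}: ragged node arrays")
        if not np.all(np.isfinite(self.xyz)):
            raise MorphologyError(f"{self.neuron_id}: non-finite coordinates")
        if self.frame not in VALID_FRAMES:
            raise FrameError(
                f"{self.neuron_id}: frame {self.frame!r} not in {VALID_FRAMES}"
            )
        if len(np.unique(self.ids)) != n:
            raise MorphologyError(f"{self.neuron_id}: duplicate sample ids")
        nonroot = self.parent_index != ROOT_PARENT
        if np.any(self.parent_index[nonroot] < 0) or np.any(
            self.parent_index >= n
        ):
            raise MorphologyError(f"{self.neuron_id}: parent index out of range")
        # parent-before-child ordering doubles as an acyclicity proof
        order = np.arange(n)
        if np.any(self.parent_index[nonroot] >= order[nonroot]):
            raise MorphologyError(
                f"{self.neuron_id}: a node precedes its parent (or a cycle exists)"
            )
        roots = self.root_indices
        if self.strict:
            if len(roots) != 1:
                names = ", ".join(str(i) for i in self.ids[roots])
                raise MorphologyError(
                    f"{self.neuron_id}: expected exactly one root, found "
                    f"{len(roots)} (sample ids: {names or 'none'})"
                )
            self._validate_soma_connectivity()

    def _validate_soma_connectivity(self) -> None:
        """Soma nodes must form a connected subgraph containing the root."""
        soma = np.flatnonzero(self.types == SOMA)
        if len(soma) == 0:
            return  # somaless fragments are tolerated (axon-only tracings)
        root = self.root_indices[0]
        if self.types[root] != SOMA:
            raise MorphologyError(f"{self.neuron_id}: root is not a soma node")
        for i in soma:
            j = i
            while j != root:
                j = self.parent_index[j]
                if j == ROOT_PARENT or self.types[j] != SOMA:
                    raise MorphologyError(
                        f"{self.neuron_id}: soma nodes are not a connected "
                        "subgraph containing the root"
                    )

    # ------------------------------------------------------------------ #
    def edge_lengths(self) -> np.ndarray:
        """Euclidean length (mm) of each parent->child edge, in edge order."""
        e = self.edges()
        return np.linalg.norm(self.xyz[e[:, 1]] - self.xyz[e[:, 0]], axis=1)

    def translated(self, delta, frame: str | None = None) -> "NeuronReconstruction":
        """Return a copy with all coordinates shifted by ``delta`` (mm)."""
        return NeuronReconstruction(
            neuron_id=self.neuron_id,
            ids=self.ids.copy(),
            parent_index=self.parent_index.copy(),
            types=self.types.copy(),
            xyz=self.xyz + np.asarray(delta, dtype=float),
            radius_um=self.radius_um.copy(),
            frame=frame or self.frame,
            provenance=dict(self.provenance),
            strict=self.strict,
        )

    def relabeled(self, new_ids: Iterable[int]) -> "NeuronReconstruction":
        """Return a copy with different sample ids (same topology)."""
        return NeuronReconstruction(
            neuron_id=self.neuron_id,
            ids=np.asarray(list(new_ids)),
            parent_index=self.parent_index.copy(),
            types=self.types.copy(),
            xyz=self.xyz.copy(),
            radius_um=self.radius_um.copy(),
            frame=self.frame,
            provenance=dict(self.provenance),
            strict=self.strict,
        )


class MorphologyBuilder:
    """Incremental construction helper used by the generators and stitcher."""

    def __init__(self, neuron_id: str, frame: str = "bregma") -> None:
        self.neuron_id = neuron_id
        self.frame = frame
        self._parents: list[int] = []
        self._types: list[int] = []
        self._xyz: list[tuple[float, float, float]] = []
        self._radius: list[float] = []

    def add_node(
        self,
        parent: int,
        node_type: int,
        point,
        radius_um: float = float("nan"),
    ) -> int:
        """Append a node; ``parent`` is a previously returned index or -1."""
        idx = len(self._parents)
        if parent >= idx:
            raise MorphologyError("parent must be added before its child")
        self._parents.append(int(parent))
        self._types.append(int(node_type))
        p = tuple(float(c) for c in point)
        if len(p) != 3:
            raise ValueError("point must have 3 coordinates (ml, ap, dv)")
        self._xyz.append(p)
        self._radius.append(float(radius_um))
        return idx

    def add_chain(
        self, parent: int, node_type: int, points, radius_um: float = float("nan")
    ) -> int:
        """Append a polyline of nodes; returns the index of the last one."""
        for p in points:
            parent = self.add_node(parent, node_type, p, radius_um)
        return parent

    def build(self, strict: bool = True, provenance: dict | None = None) -> NeuronReconstruction:
        n = len(self._parents)
        return NeuronReconstruction(
            neuron_id=self.neuron_id,
            ids=np.arange(1, n + 1),
            parent_index=np.array(self._parents, dtype=np.int64),
            types=np.array(self._types, dtype=np.int64),
            xyz=np.array(self._xyz, dtype=np.float64),
            radius_um=np.array(self._radius, dtype=np.float64),
            frame=self.frame,
            provenance=provenance or {},
            strict=strict,
        )
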