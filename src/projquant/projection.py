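"""Per-neuron projection profiles and cell-by-region projection matrices.

"Branching axon" in a region is operationalized per connected component of
the region-restricted axonal cable: a component that contains at least one
axonal branch point (an axon node with >= 2 axon children) located inside the
region counts as branching (target) axon; components without an intra-region
branch point count as passing (fiber-of-passage) cable and are tallied
separately, so users can sum both if desired. Cable in no model region
accrues to ``elsewhere``. The three tallies always sum to the total axonal
cable length (checked on construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import AXON, FrameError, NeuronReconstruction
from .regions import (
    ELSEWHERE,
    RegionModel,
    _crossing_parameters,
    locate_points,
)

CLASS_NONE = "none"
CLASS_LIGHT = "light"
CLASS_DARK = "dark"

#: default class thresholds (mm of branching axon in the target region)
LIGHT_THRESHOLD_MM = 1.0
DARK_THRESHOLD_MM = 10.0

CORE_REGIONS = ("wS1", "wS2", "wM1/2")


class UndefinedResultError(ZeroDivisionError):
    """A ratio was requested for a neuron with an empty denominator."""


@dataclass
class ProjectionProfile:
    """Branching/passing axonal cable (mm) per region for one neuron."""

    neuron_id: str
    region_lengths: dict[str, float]
    passing_lengths: dict[str, float]
    elsewhere_length: float
    total_axon_length: float

    def __post_init__(self) -> None:
        vals = [
            *self.region_lengths.values(),
            *self.passing_lengths.values(),
            self.elsewhere_length,
            self.total_axon_length,
        ]
        if any(v < 0 for v in vals):
            raise ValueError(f"{self.neuron_id}: negative cable length")
        assigned = (
            sum(self.region_lengths.values())
            + sum(self.passing_lengths.values())
            + self.elsewhere_length
        )
        tol = 1e-9 * max(1.0, self.total_axon_length)
        if abs(assigned - self.total_axon_length) > tol:
            raise ValueError(
                f"{self.neuron_id}: cable not conserved "
                f"({assigned} vs {self.total_axon_length})"
            )

    def branching_total(self) -> float:
        return sum(self.region_lengths.values())


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[int, int] = {}

    def find(self, x: int) -> int:
        p = self.parent.setdefault(x, x)
        while p != self.parent[p]:
            self.parent[p] = self.parent[self.parent[p]]
            p = self.parent[p]
        self.parent[x] = p
        return p

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def quantify_projection(
    neuron: NeuronReconstruction, model: RegionModel
) -> ProjectionProfile:
    """Assign every axonal edge's cable to regions and split it into
    branching vs passing components (see module docstring for the rule)."""
    if neuron.frame != "bregma":
        raise FrameError(
            f"{neuron.neuron_id}: projection quantification requires the "
            f"bregma frame, got {neuron.frame!r}"
        )

    edges = neuron.edges()
    axon_edges = edges[neuron.types[edges[:, 1]] == AXON]

    # (region, key_a, key_b, length) for every region-homogeneous piece;
    # keys are node indices, with fresh keys for boundary-crossing points
    pieces: list[tuple[str, int, int, float]] = []
    next_key = neuron.n_nodes
    for u, v in axon_edges:
        p0, p1 = neuron.xyz[u], neuron.xyz[v]
        seg_len = float(np.linalg.norm(p1 - p0))
        if seg_len == 0.0:
            continue
        ts = np.concatenate([[0.0], _crossing_parameters(p0, p1, model), [1.0]])
        keys = [int(u)] + list(range(next_key, next_key + len(ts) - 2)) + [int(v)]
        next_key += len(ts) - 2
        mids = p0 + np.outer((ts[:-1] + ts[1:]) / 2.0, p1 - p0)
        labels = locate_points(mids, model)
        lengths = seg_len * np.diff(ts)
        for k in range(len(labels)):
            pieces.append((labels[k], keys[k], keys[k + 1], float(lengths[k])))

    # axonal branch points and the region each one sits in
    axon_child_counts = np.zeros(neuron.n_nodes, dtype=int)
    np.add.at(axon_child_counts, axon_edges[:, 0], 1)
    is_branch = (neuron.types == AXON) & (axon_child_counts >= 2)
    branch_idx = np.flatnonzero(is_branch)
    branch_region = dict(
        zip(branch_idx.tolist(), locate_points(neuron.xyz[branch_idx], model))
    ) if len(branch_idx) else {}

    region_names = model.names
    branching = {name: 0.0 for name in region_names}
    passing = {name: 0.0 for name in region_names}
    elsewhere = 0.0
    total = 0.0

    by_region: dict[str, list[tuple[int, int, float]]] = {}
    for label, a, b, ln in pieces:
        total += ln
        if label == ELSEWHERE:
            elsewhere += ln
        else:
            by_region.setdefault(label, []).append((a, b, ln))

    for name, rp in by_region.items():
        uf = _UnionFind()
        for a, b, _ in rp:
            uf.union(a, b)
        comp_len: dict[int, float] = {}
        for a, b, ln in rp:
            comp_len[uf.find(a)] = comp_len.get(uf.find(a), 0.0) + ln
        comp_branching: set[int] = set()
        for b_idx, b_reg in branch_region.items():
            if b_reg == name and b_idx in uf.parent:
                comp_branching.add(uf.find(b_idx))
        for root, ln in comp_len.items():
            if root in comp_branching:
                branching[name] += ln
            else:
                passing[name] += ln

    return ProjectionProfile(
        neuron_id=neuron.neuron_id,
        region_lengths=branching,
        passing_lengths=passing,
        elsewhere_length=elsewhere,
        total_axon_length=total,
    )


# --------------------------------------------------------------------------- #
# thresholded matrix and classification
# --------------------------------------------------------------------------- #
def classify_length(
    length_mm: float,
    light_mm: float = LIGHT_THRESHOLD_MM,
    dark_mm: float = DARK_THRESHOLD_MM,
) -> str:
    """Class of one (neuron, region) cell: strict thresholds, ``dark`` for
    > ``dark_mm``, ``light`` for > ``light_mm``, else ``none``; boundary
    values fall to the lower class."""
    if light_mm < 0 or dark_mm < 0:
        raise ValueError("thresholds must be non-negative")
    if not light_mm < dark_mm:
        raise ValueError("light threshold must be below dark threshold")
    if length_mm > dark_mm:
        return CLASS_DARK
    if length_mm > light_mm:
        return CLASS_LIGHT
    return CLASS_NONE


@dataclass
class ProjectionMatrix:
    """Neurons x regions class matrix ({none, light, dark})."""

    neurons: list[str]
    regions: list[str]
    classes: np.ndarray  # (n_neurons, n_regions) of strings
    thresholds: tuple[float, float] = (LIGHT_THRESHOLD_MM, DARK_THRESHOLD_MM)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.classes, index=self.neurons, columns=self.regions)


def threshold_matrix(
    profiles: list[ProjectionProfile],
    light_mm: float = LIGHT_THRESHOLD_MM,
    dark_mm: float = DARK_THRESHOLD_MM,
    regions: list[str] | None = None,
) -> ProjectionMatrix:
    """Thresholded cell-by-region matrix from branching-axon lengths."""
    if not profiles:
        raise ValueError("need at least one profile")
    if regions is None:
        regions = list(profiles[0].region_lengths)
    classes = np.array(
        [
            [
                classify_length(p.region_lengths.get(r, 0.0), light_mm, dark_mm)
                for r in regions
            ]
            for p in profiles
        ],
        dtype=object,
    )
    return ProjectionMatrix(
        neurons=[p.neuron_id for p in profiles],
        regions=regions,
        classes=classes,
        thresholds=(light_mm, dark_mm),
    )


S2P = "S2p"
M1P = "M1p"
UNCLASSIFIED = "unclassified"


def classify_projection_class(profile: ProjectionProfile) -> str:
    """S2p vs M1p by the dominant of the two major targets (wS2 vs wM1/2).

    Exact ties — including no cable in either region — are ``unclassified``.
    The label is invariant to rescaling all lengths by a positive constant.
    """
    try:
        s2 = profile.region_lengths["wS2"]
        m1 = profile.region_lengths["wM1/2"]
    except KeyError as exc:
        raise ValueError(
            f"{profile.neuron_id}: profile lacks region {exc} required for "
            "classification"
        ) from None
    if s2 > m1:
        return S2P
    if m1 > s2:
        return M1P
    return UNCLASSIFIED


def core_fraction(profile: ProjectionProfile) -> float:
    """Fraction of branching axon in the core targets wS1 + wS2 + wM1/2."""
    total = profile.branching_total()
    if total <= 0:
        raise UndefinedResultError(
            f"{profile.neuron_id}: no branching axon; core fraction undefined"
        )
    core = sum(profile.region_lengths.get(r, 0.0) for r in CORE_REGIONS)
    return core / total


# --------------------------------------------------------------------------- #
# group summaries
# --------------------------------------------------------------------------- #
def group_summary(
    profiles: list[ProjectionProfile],
    summaries: list,
    labels: list[str],
) -> pd.DataFrame:
    """Per-group mean and sample SD of every morphometric and per-region length.

    ``summaries`` are :class:`~projquant.morphometry.MorphometrySummary`
    objects aligned with ``profiles``; ``labels`` assigns every neuron to a
    group (e.g. S2p / M1p). SD uses the n-1 (sample) convention and is NaN
    for single-neuron groups.
    """
    if not (len(profiles) == len(summaries) == len(labels)):
        raise ValueError("profiles, summaries and labels must align")
    if len(profiles) == 0:
        raise ValueError("cannot summarise an empty group")

    records = []
    for p, s, lab in zip(profiles, summaries, labels):
        rec = {
            "group": lab,
            "dendritic_length_mm": s.dendritic_length_mm,
            "n_stems": s.n_stems,
            "n_branch_points": s.n_branch_points,
            "axonal_length_mm": s.axonal_length_mm,
        }
        for r, v in p.region_lengths.items():
            rec[f"branching_{r}_mm"] = v
        records.append(rec)
    df = pd.DataFrame(records)
    agg = df.groupby("group").agg(["mean", lambda x: x.std(ddof=1), "count"])
    agg.columns = [
        f"{metric}_{ {'mean': 'mean', '<lambda_0>': 'sd', 'count': 'n'}[stat] }"
        for metric, stat in agg.columns
    ]
    return agg
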