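"""Synthetic reconstructions and density volumes with exact ground truth.

The generator emulates the statistical structure of L2/3 pyramidal
projection neurons of the whisker primary somatosensory cortex (wS1):

* soma 200-250 µm below the pia in the C2 barrel column;
* ~8 mm of dendrite on ~8 stems with ~60-65 branch nodes;
* ~40 mm of dense, branched local axon inside wS1;
* a descending trunk that runs through the white matter and emits
  long-range collaterals, each terminating in a branched arbor of an
  exactly specified cable length planted strictly inside one target region
  (or an unbranched fiber of passage for regions that receive cable
  without arborization);
* multi-animal Gaussian density hotspots at specified centres for the
  bulk-labeling arm.

Geometry is schematic (serpentine space-filling polylines, straight
trunks): only the quantities the pipeline measures — cable lengths per
compartment and per region, stem and branch counts, topology — are
controlled, and those are controlled exactly. Every generator is
deterministic given its seed. Ground-truth profiles are computed from the
construction itself, never by running the quantification being tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .density import DensityVolume, GridSpec
from .morphology import (
    APICAL_DENDRITE,
    AXON,
    BASAL_DENDRITE,
    ROOT_PARENT,
    SOMA,
    MorphologyBuilder,
    NeuronReconstruction,
)
from .projection import ProjectionMatrix, ProjectionProfile, threshold_matrix
from .regions import (
    DEFAULT_INJECTION_SITE,
    DEFAULT_PROJECTION_CENTERS,
    InjectionSite,
    RegionModel,
    default_region_model,
    effective_interior_box,
    locate_point,
)
from .stitching import Section, SectionStack


class SpecError(ValueError):
    """A synthetic specification is infeasible or inconsistent."""


# --------------------------------------------------------------------------- #
# exact-length path primitives
# --------------------------------------------------------------------------- #
def serpentine_path(
    start,
    bounds,
    length: float,
    row_step: float = 0.025,
    layer_step: float = 0.05,
) -> list[np.ndarray]:
    """Vertices (excluding ``start``) of a boustrophedon polyline of exactly
    ``length`` mm confined to the axis-aligned ``bounds`` ((2, 3) min/max).

    The path sweeps rows along the ml axis, advancing by ``row_step`` along
    ap, stacking layers along dv. Raises :class:`SpecError` if the box
    cannot accommodate the requested length.
    """
    lo = np.asarray(bounds, float)[0]
    hi = np.asarray(bounds, float)[1]
    cur = np.asarray(start, dtype=float).copy()
    if np.any(cur < lo - 1e-12) or np.any(cur > hi + 1e-12):
        raise SpecError("serpentine start point lies outside its box")
    cur = np.clip(cur, lo, hi)

    points: list[np.ndarray] = []
    remaining = float(length)
    if remaining <= 0:
        raise SpecError("serpentine length must be positive")

    row_dir = 1.0  # along ml
    col_dir = 1.0  # along ap
    # stack dv layers toward the larger free side of the band
    layer_dir = 1.0 if (hi[2] - cur[2]) >= (cur[2] - lo[2]) else -1.0
    max_moves = int(length / min(row_step, layer_step) * 4 + 1000)

    def advance(target: np.ndarray) -> bool:
        """Move toward target; returns True when the length budget is spent."""
        nonlocal cur, remaining
        step = float(np.linalg.norm(target - cur))
        if step <= 0:
            return False
        if step >= remaining - 1e-15:
            cur = cur + (target - cur) * (remaining / step)
            points.append(cur.copy())
            remaining = 0.0
            return True
        cur = target
        points.append(cur.copy())
        remaining -= step
        return False

    for _ in range(max_moves):
        # sweep a row along ml
        row_target = cur.copy()
        row_target[0] = hi[0] if row_dir > 0 else lo[0]
        if advance(row_target):
            return points
        row_dir = -row_dir
        # advance along ap, or start a new dv layer when the plane is full
        if (col_dir > 0 and cur[1] + row_step <= hi[1] + 1e-12) or (
            col_dir < 0 and cur[1] - row_step >= lo[1] - 1e-12
        ):
            col_target = cur.copy()
            col_target[1] = min(hi[1], max(lo[1], cur[1] + col_dir * row_step))
            if advance(col_target):
                return points
        else:
            col_dir = -col_dir
            nxt = cur[2] + layer_dir * layer_step
            if not (lo[2] - 1e-12 <= nxt <= hi[2] + 1e-12):
                raise SpecError(
                    f"box of size {np.round(hi - lo, 3)} cannot hold "
                    f"{length:.2f} mm of cable at the configured spacing"
                )
            layer_target = cur.copy()
            layer_target[2] = min(hi[2], max(lo[2], nxt))
            if advance(layer_target):
                return points
    raise SpecError("serpentine failed to converge (length budget too large)")


def _attach_serpentine(
    builder: MorphologyBuilder,
    parent: int,
    node_type: int,
    start,
    bounds,
    length: float,
) -> int:
    pts = serpentine_path(start, bounds, length)
    return builder.add_chain(parent, node_type, pts)


def _attach_branched_arbor(
    builder: MorphologyBuilder,
    parent: int,
    node_type: int,
    root_point,
    bounds,
    length: float,
) -> None:
    """Grow a branched arbor of exactly ``length`` mm inside ``bounds``.

    A short initial segment leads to a bifurcation node strictly inside the
    box; two serpentine daughters fill the two ap halves of the box. The
    bifurcation guarantees at least one branch point inside the region.
    """
    lo = np.asarray(bounds, float)[0]
    hi = np.asarray(bounds, float)[1]
    root = np.asarray(root_point, dtype=float)
    eps = min(0.01, length / 4.0)
    center = (lo + hi) / 2.0
    direction = center - root
    norm = float(np.linalg.norm(direction))
    fork_point = root if norm == 0 else root + direction * (eps / norm)
    fork = builder.add_node(parent, node_type, fork_point)
    consumed = float(np.linalg.norm(fork_point - root))
    half = (length - consumed) / 2.0
    if half <= 0:
        raise SpecError("arbor length too small to realise a branch point")
    mid_ap = fork_point[1]
    lower = np.array([lo, [hi[0], max(mid_ap, lo[1] + 1e-6), hi[2]]])
    upper = np.array([[lo[0], min(mid_ap, hi[1] - 1e-6), lo[2]], hi])
    _attach_serpentine(builder, fork, node_type, fork_point, lower, half)
    _attach_serpentine(builder, fork, node_type, fork_point, upper, half)


# --------------------------------------------------------------------------- #
# single-neuron specification and generation
# --------------------------------------------------------------------------- #
@dataclass
class SyntheticNeuronSpec:
    """Planted ground truth for one synthetic L2/3 projection neuron.

    ``collaterals`` are (region name, branching length mm, include_branch)
    triples: with ``include_branch`` the planted cable arborizes inside the
    region (branching axon); without it the same length is planted as an
    unbranched fiber (passing cable). ``passing_fibers`` is shorthand for
    the latter. All planted lengths are realised exactly.
    """

    neuron_id: str = "synthetic"
    soma: tuple[float, float, float] = (
        DEFAULT_INJECTION_SITE[0],
        DEFAULT_INJECTION_SITE[1],
        0.225,
    )
    dendrite_length_mm: float = 8.1
    n_stems: int = 8
    n_dendrite_branch_points: int = 64
    local_axon_mm: float = 41.7
    collaterals: list[tuple[str, float, bool]] = field(default_factory=list)
    passing_fibers: list[tuple[str, float]] = field(default_factory=list)
    rng_seed: int = 0

    def validate(self, model: RegionModel) -> None:
        if self.dendrite_length_mm < 0 or self.local_axon_mm < 0:
            raise SpecError("lengths must be non-negative")
        if self.n_stems < 0 or self.n_dendrite_branch_points < 0:
            raise SpecError("counts must be non-negative")
        if self.n_stems == 0 and self.n_dendrite_branch_points > 0:
            raise SpecError("branch points require at least one stem")
        twig = _TWIG_LEN * self.n_dendrite_branch_points
        if self.dendrite_length_mm > 0 and self.n_stems > 0:
            backbone = self.dendrite_length_mm - twig
            if backbone <= 0.01 * self.n_stems:
                raise SpecError(
                    f"{self.n_dendrite_branch_points} dendritic branch points "
                    f"are not realisable within {self.dendrite_length_mm} mm"
                )
        names = set(model.names)
        for region, length, _ in self.collaterals:
            if region not in names:
                raise SpecError(f"collateral region {region!r} not in model")
            if length <= 0.1:
                raise SpecError(
                    f"planted collateral in {region} must exceed 0.1 mm"
                )
        for region, length in self.passing_fibers:
            if region not in names:
                raise SpecError(f"passing-fiber region {region!r} not in model")
            if length <= 0.1:
                raise SpecError(
                    f"planted passing fiber in {region} must exceed 0.1 mm"
                )


_TWIG_LEN = 0.02  # mm, dendritic side-twig realising one branch point
_WM_CLEARANCE = 0.15  # mm below the deepest cortical region for trunk routing


def _white_matter_depth(model: RegionModel) -> float:
    """A trunk-routing depth below all cortical boxes and above subcortical ones."""
    cortical_max = max(
        (r.dv_max for r in model.regions if r.shape == "cortical_column"),
        default=1.2,
    )
    depth = cortical_max + _WM_CLEARANCE
    for r in model.regions:
        if r.dv_min <= depth <= r.dv_max:
            raise SpecError(
                f"no region-free white-matter band: {r.name} spans dv {depth}"
            )
    return depth


def _grow_dendrites(
    builder: MorphologyBuilder, spec: SyntheticNeuronSpec, rng: np.random.Generator
) -> float:
    """Plant stems/branch points/length exactly; returns total dendritic mm."""
    k = spec.n_stems
    if k == 0 or spec.dendrite_length_mm <= 0:
        return 0.0
    B = spec.n_dendrite_branch_points
    backbone_total = spec.dendrite_length_mm - B * _TWIG_LEN
    per_stem_b = [B // k + (1 if i < B % k else 0) for i in range(k)]
    per_stem_len = backbone_total / k
    soma = np.asarray(spec.soma)

    for i in range(k):
        theta = 2.0 * np.pi * i / k + rng.uniform(-0.1, 0.1)
        apical = i == 0
        node_type = APICAL_DENDRITE if apical else BASAL_DENDRITE
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        if apical:
            # ascend toward the pia, then run horizontally just below it
            up_len = min(soma[2] - 0.03, per_stem_len)
            waypoints = [soma + np.array([0, 0, -up_len])]
            rest = per_stem_len - up_len
            if rest > 0:
                waypoints.append(waypoints[0] + radial * rest)
        else:
            tilt = np.array([0.0, 0.0, 0.1])
            d = radial + tilt
            d /= np.linalg.norm(d)
            waypoints = [soma + d * per_stem_len]

        # vertices along the backbone at the twig-attachment arc positions
        path = [soma, *waypoints]
        seg_lens = [
            float(np.linalg.norm(b - a)) for a, b in zip(path[:-1], path[1:])
        ]
        total = sum(seg_lens)
        b_i = per_stem_b[i]
        marks = [total * (m + 1) / (b_i + 1) for m in range(b_i)]
        perp = np.array([-radial[1], radial[0], 0.0])

        parent = 0  # soma node index
        walked = 0.0
        mark_iter = iter(marks)
        next_mark = next(mark_iter, None)
        for a, b, sl in zip(path[:-1], path[1:], seg_lens):
            while next_mark is not None and walked < next_mark <= walked + sl:
                frac = (next_mark - walked) / sl
                v = a + (b - a) * frac
                parent = builder.add_node(parent, node_type, v)
                sign = 1.0 if (int(next_mark / total * 1000) % 2 == 0) else -1.0
                builder.add_node(parent, node_type, v + perp * _TWIG_LEN * sign)
                next_mark = next(mark_iter, None)
            parent = builder.add_node(parent, node_type, b)
            walked += sl
    return spec.dendrite_length_mm


def generate_neuron(
    spec: SyntheticNeuronSpec,
    model: RegionModel | None = None,
    validate: bool = True,
) -> tuple[NeuronReconstruction, ProjectionProfile]:
    """Build one synthetic neuron plus its analytically known projection profile.

    The profile's ``region_lengths`` equal the planted branching lengths
    exactly (the local wS1 axon including the descending trunk's intra-wS1
    run, and each collateral's arbor plus its short intra-region entry);
    ``passing_lengths`` equal the planted fiber lengths; everything else
    (white-matter trunk and horizontal routing) is ``elsewhere``.
    """
    model = model or default_region_model()
    spec.validate(model)
    rng = np.random.default_rng(spec.rng_seed)
    builder = MorphologyBuilder(spec.neuron_id, frame="bregma")
    soma = np.asarray(spec.soma, dtype=float)
    soma_idx = builder.add_node(ROOT_PARENT, SOMA, soma, radius_um=7.0)

    dend_len = _grow_dendrites(builder, spec, rng)

    branching = {name: 0.0 for name in model.names}
    passing = {name: 0.0 for name in model.names}
    elsewhere = 0.0
    total_axon = 0.0

    has_axon = (
        spec.local_axon_mm > 0 or spec.collaterals or spec.passing_fibers
    )
    if has_axon:
        ws1 = model["wS1"]
        if locate_point(soma, model) != "wS1":
            raise SpecError("soma must lie inside the wS1 region")
        wm_depth = _white_matter_depth(model)

        # descending trunk: soma -> mid-cortex attach point -> wS1 floor -> WM
        attach_dv = min(max(0.5, soma[2] + 0.1), ws1.dv_max - 0.1)
        trunk_pts = [
            soma + np.array([0, 0, attach_dv - soma[2]]),
            np.array([soma[0], soma[1], ws1.dv_max]),
            np.array([soma[0], soma[1], wm_depth]),
        ]
        attach_idx = builder.add_node(soma_idx, AXON, trunk_pts[0])
        floor_idx = builder.add_node(attach_idx, AXON, trunk_pts[1])
        hub_idx = builder.add_node(floor_idx, AXON, trunk_pts[2])
        trunk_in_ws1 = ws1.dv_max - soma[2]
        trunk_below = wm_depth - ws1.dv_max
        total_axon += trunk_in_ws1 + trunk_below
        elsewhere += trunk_below

        # dense local axon: fills the priority-free interior of wS1
        if spec.local_axon_mm > 0:
            attach_pt = trunk_pts[0]
            try:
                ibox = effective_interior_box(
                    model, "wS1", containing=(attach_pt[0], attach_pt[1])
                )
            except ValueError as exc:
                raise SpecError(
                    "soma column lies outside the wS1 interior free of "
                    f"higher-priority regions ({exc}); move the soma or the "
                    "model"
                ) from None
            arbor_len = spec.local_axon_mm - trunk_in_ws1
            if arbor_len <= 0.02:
                raise SpecError(
                    f"local axon ({spec.local_axon_mm} mm) must exceed the "
                    f"intra-wS1 trunk run ({trunk_in_ws1:.3f} mm)"
                )
            if not ibox[0][2] <= attach_pt[2] <= ibox[1][2]:
                raise SpecError(
                    "local-axon attachment depth falls outside the wS1 "
                    "interior dv band"
                )
            _attach_branched_arbor(
                builder, attach_idx, AXON, attach_pt, ibox, arbor_len
            )
            total_axon += arbor_len
            branching["wS1"] += spec.local_axon_mm

        # long-range collaterals and fibers of passage
        planted = [(r, ln, br) for (r, ln, br) in spec.collaterals]
        planted += [(r, ln, False) for (r, ln) in spec.passing_fibers]
        for region_name, length, include_branch in planted:
            region = model[region_name]
            ibox = effective_interior_box(model, region_name)
            cx = (ibox[0][0] + ibox[1][0]) / 2.0
            cy = (ibox[0][1] + ibox[1][1]) / 2.0
            if region.dv_max < wm_depth:  # cortical target: approach from below
                entry = np.array([cx, cy, region.dv_max - 0.05])
            elif region.dv_min > wm_depth:  # subcortical: approach from above
                entry = np.array([cx, cy, region.dv_min + 0.05])
            else:
                raise SpecError(
                    f"{region_name}: dv band overlaps the white-matter "
                    "routing depth"
                )
            run_pt = np.array([cx, cy, wm_depth])
            run_idx = builder.add_node(hub_idx, AXON, run_pt)
            entry_idx = builder.add_node(run_idx, AXON, entry)
            run_len = float(np.linalg.norm(run_pt - trunk_pts[2]))
            riser_len = float(np.linalg.norm(entry - run_pt))
            inside = 0.05  # riser cable between the region face and `entry`
            elsewhere += run_len + riser_len - inside
            total_axon += run_len + riser_len
            remainder = length - inside
            if include_branch:
                _attach_branched_arbor(
                    builder, entry_idx, AXON, entry, ibox, remainder
                )
                branching[region_name] += length
            else:
                _attach_serpentine(
                    builder, entry_idx, AXON, entry, ibox, remainder
                )
                passing[region_name] += length
            total_axon += remainder

    neuron = builder.build(
        provenance={"generator": "projquant.synthetic", "seed": spec.rng_seed}
    )
    profile = ProjectionProfile(
        neuron_id=spec.neuron_id,
        region_lengths=branching,
        passing_lengths=passing,
        elsewhere_length=elsewhere,
        total_axon_length=total_axon,
    )

    if validate:
        _validate_construction(neuron, spec, model, dend_len)
    return neuron, profile


def _validate_construction(
    neuron: NeuronReconstruction,
    spec: SyntheticNeuronSpec,
    model: RegionModel,
    dend_len: float,
) -> None:
    """Guard: planted geometry must land where the ground truth says it does."""
    from .morphometry import cable_length, count_branch_points, count_stems

    if abs(cable_length(neuron, "dendrite") - dend_len) > 1e-9 * max(1, dend_len):
        raise SpecError("dendritic length was not realised exactly")
    if count_stems(neuron, "dendrite") != spec.n_stems:
        raise SpecError("stem count was not realised")
    if count_branch_points(neuron, "dendrite") != spec.n_dendrite_branch_points:
        raise SpecError("dendritic branch-point count was not realised")


# --------------------------------------------------------------------------- #
# cohorts
# --------------------------------------------------------------------------- #
#: per-class, per-region (mean mm, SD mm, zero-inflation probability, floor mm)
#: defaults emulating the S2p/M1p projection statistics of the wS1 L2/3 system
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "S2p": {
        "wS1": (41.7, 1.1, 0.0, 30.0),
        "wS2": (12.2, 7.4, 0.0, 0.5),
        "wM1/2": (0.0, 0.0, 1.0, 0.0),
        "Striatum": (6.0, 5.0, 0.5, 0.2),
        "TeA": (4.0, 3.0, 0.8, 0.2),
        "PL1": (2.0, 1.5, 0.7, 0.2),
        "PL2": (2.0, 1.5, 0.7, 0.2),
        "PM": (2.0, 2.0, 0.5, 0.2),
        "CM": (1.5, 1.5, 0.8, 0.2),
        "AM": (2.0, 2.0, 0.7, 0.2),
        "PP": (1.5, 1.0, 0.8, 0.2),
    },
    "M1p": {
        "wS1": (40.0, 3.8, 0.0, 30.0),
        "wS2": (1.6, 2.7, 0.67, 0.2),
        "wM1/2": (20.8, 11.7, 0.0, 2.0),
        "Striatum": (6.0, 5.0, 0.67, 0.2),
        "TeA": (4.0, 3.0, 0.8, 0.2),
        "PL1": (2.0, 1.5, 0.7, 0.2),
        "PL2": (2.0, 1.5, 0.7, 0.2),
        "PM": (3.0, 3.0, 0.6, 0.2),
        "CM": (3.0, 3.0, 0.6, 0.2),
        "AM": (2.0, 2.0, 0.7, 0.2),
        "PP": (1.5, 1.0, 0.8, 0.2),
    },
}

#: morphometric targets per class: (dendrite mm sd, stems mean sd, nodes mean sd)
DEFAULT_MORPHOMETRY_PARAMS = {
    "S2p": {"dendrite": (8.1, 0.8), "stems": (8.3, 1.6), "nodes": (64.0, 10.0)},
    "M1p": {"dendrite": (8.5, 0.7), "stems": (8.0, 1.4), "nodes": (63.0, 4.0)},
}


@dataclass
class SyntheticCohortSpec:
    """A planted cohort of S2p and M1p neurons."""

    n_s2p: int = 6
    n_m1p: int = 9
    class_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_CLASS_PARAMS.items()
        }
    )
    morphometry_params: dict = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_MORPHOMETRY_PARAMS.items()
        }
    )
    core_fraction_floor: float = 0.78
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_s2p < 0 or self.n_m1p < 0:
            raise SpecError("cohort sizes must be non-negative")
        for cls, params in self.class_params.items():
            for region, (mean, sd, p0, floor) in params.items():
                if sd < 0 or floor < 0:
                    raise SpecError(f"{cls}/{region}: SD and floor must be >= 0")
                if not 0.0 <= p0 <= 1.0:
                    raise SpecError(f"{cls}/{region}: zero-inflation not in [0,1]")


@dataclass
class SyntheticCohort:
    neurons: list[NeuronReconstruction]
    profiles: list[ProjectionProfile]  # planted ground truth
    labels: list[str]
    matrix: ProjectionMatrix  # planted design matrix


def _draw_truncated(rng, mean, sd, floor, max_tries=1000) -> float:
    """Normal draw truncated below at ``floor`` (rejection sampling)."""
    if sd == 0:
        if mean < floor:
            raise SpecError(f"degenerate draw: mean {mean} below floor {floor}")
        return float(mean)
    for _ in range(max_tries):
        v = float(rng.normal(mean, sd))
        if v >= floor:
            return v
    raise SpecError("truncated draw failed (floor too far above the mean)")


def generate_cohort(
    spec: SyntheticCohortSpec | None = None,
    model: RegionModel | None = None,
) -> SyntheticCohort:
    """Draw a cohort with zero-inflated truncated-normal per-region lengths.

    Class identity is enforced on the draws (an M1p neuron's wS2 cable is
    redrawn while it would exceed its wM1/2 cable): the classes are defined
    experimentally by retrograde labeling from the dominant target, so a
    planted cohort member must satisfy its class-defining inequality.
    Minor-region draws are rescaled, when necessary, so that wS1+wS2+wM1/2
    retain at least ``core_fraction_floor`` of each neuron's branching axon.
    """
    spec = spec or SyntheticCohortSpec()
    spec.validate()
    model = model or default_region_model()
    rng = np.random.default_rng(spec.rng_seed)
    seeds = rng.integers(0, 2**31 - 1, size=spec.n_s2p + spec.n_m1p)

    neurons, profiles, labels = [], [], []
    order = ["S2p"] * spec.n_s2p + ["M1p"] * spec.n_m1p
    for i, cls in enumerate(order):
        params = spec.class_params[cls]
        draws: dict[str, float] = {}
        for region, (mean, sd, p0, floor) in params.items():
            if rng.random() < p0:
                draws[region] = 0.0
            else:
                draws[region] = _draw_truncated(rng, mean, sd, floor)
        if cls == "M1p":
            for _ in range(1000):
                if draws["wS2"] < draws["wM1/2"]:
                    break
                _, sd, p0, floor = params["wS2"]
                mean = params["wS2"][0]
                draws["wS2"] = (
                    0.0 if rng.random() < p0
                    else _draw_truncated(rng, mean, sd, floor)
                )
            else:
                draws["wS2"] = 0.0

        core = sum(draws.get(r, 0.0) for r in ("wS1", "wS2", "wM1/2"))
        minor = sum(v for r, v in draws.items() if r not in ("wS1", "wS2", "wM1/2"))
        budget = core * (1.0 / spec.core_fraction_floor - 1.0)
        if minor > budget and minor > 0:
            scale = budget / minor
            for r in draws:
                if r not in ("wS1", "wS2", "wM1/2"):
                    draws[r] = 0.0 if draws[r] * scale < 0.15 else draws[r] * scale

        mp = spec.morphometry_params[cls]
        n_stems = max(1, int(round(rng.normal(*mp["stems"]))))
        n_nodes = max(0, int(round(rng.normal(*mp["nodes"]))))
        dend = max(1.0, rng.normal(*mp["dendrite"]))
        neuron_spec = SyntheticNeuronSpec(
            neuron_id=f"{cls}_{i:02d}",
            soma=(
                DEFAULT_INJECTION_SITE[0],
                DEFAULT_INJECTION_SITE[1],
                float(rng.uniform(0.2, 0.25)),
            ),
            dendrite_length_mm=float(dend),
            n_stems=n_stems,
            n_dendrite_branch_points=n_nodes,
            local_axon_mm=draws.get("wS1", 0.0),
            collaterals=[
                (r, v, True)
                for r, v in draws.items()
                if r != "wS1" and v > 0.0
            ],
            rng_seed=int(seeds[i]),
        )
        neuron, profile = generate_neuron(neuron_spec, model)
        neurons.append(neuron)
        profiles.append(profile)
        labels.append(cls)

    matrix = (
        threshold_matrix(profiles, regions=model.names)
        if profiles
        else ProjectionMatrix([], model.names, np.empty((0, len(model.names)),
                                                        dtype=object))
    )
    return SyntheticCohort(neurons, profiles, labels, matrix)


# --------------------------------------------------------------------------- #
# sectioning (the inverse of stitching, for round-trip testing)
# --------------------------------------------------------------------------- #
def split_into_sections(
    neuron: NeuronReconstruction,
    thickness_mm: float = 0.08,
    jitter_mm: float = 0.0,
    seed: int = 0,
) -> SectionStack:
    """Cut a reconstruction into coronal-section fragments at dv planes.

    Every edge is split at the section planes it crosses (cut points land
    exactly on the planes, so cable is conserved); each fragment keeps
    section-local dv in [0, thickness] and receives an in-plane jitter drawn
    uniformly from [-jitter, +jitter] per axis. The recorded manifest shift
    is the inverse of the jitter, so stitching can restore the original.
    """
    if thickness_mm <= 0:
        raise ValueError("section thickness must be positive")
    rng = np.random.default_rng(seed)

    def sec_of(dv: float) -> int:
        return max(0, int(np.floor(dv / thickness_mm - 1e-12)))

    # pieces per section: (section, key_parent, key_child, type, pos_p, pos_c)
    pieces: list[tuple[int, tuple, tuple, int, np.ndarray, np.ndarray]] = []
    edges = neuron.edges()
    for eid, (u, v) in enumerate(edges):
        p0, p1 = neuron.xyz[u], neuron.xyz[v]
        lo_dv, hi_dv = sorted((p0[2], p1[2]))
        k0, k1 = sec_of(lo_dv) + 1, sec_of(hi_dv)
        cut_ts = []
        for k in range(k0, k1 + 1):
            plane = k * thickness_mm
            if lo_dv < plane <= hi_dv and p1[2] != p0[2]:
                t = (plane - p0[2]) / (p1[2] - p0[2])
                if 0.0 < t < 1.0:
                    cut_ts.append(t)
        cut_ts = sorted(cut_ts)
        ts = [0.0, *cut_ts, 1.0]
        keys = (
            [("n", int(u))]
            + [("c", eid, i) for i in range(len(cut_ts))]
            + [("n", int(v))]
        )
        pos = [p0 + (p1 - p0) * t for t in ts]
        # snap cut points exactly onto their planes
        for i, t in enumerate(cut_ts):
            pos[i + 1][2] = round((p0[2] + (p1[2] - p0[2]) * t) / thickness_mm) \
                * thickness_mm
        for i in range(len(ts) - 1):
            mid_dv = (pos[i][2] + pos[i + 1][2]) / 2.0
            pieces.append(
                (
                    sec_of(mid_dv),
                    keys[i],
                    keys[i + 1],
                    int(neuron.types[v]),
                    pos[i],
                    pos[i + 1],
                )
            )

    if not pieces:  # single-node neuron
        pieces = []
        sections_present = [sec_of(neuron.xyz[0][2])]
    else:
        sections_present = sorted({p[0] for p in pieces})

    sections: list[Section] = []
    root_key = ("n", int(neuron.root_indices[0]))
    for s in sections_present:
        jitter = rng.uniform(-jitter_mm, jitter_mm, size=2) if jitter_mm > 0 \
            else np.zeros(2)
        b = MorphologyBuilder(f"{neuron.neuron_id}_s{s:03d}",
                              frame="section-local")
        local: dict[tuple, int] = {}
        sec_pieces = [p for p in pieces if p[0] == s]

        def localize(key, point, parent_local, node_type):
            if key in local:
                return local[key]
            p = point.copy()
            p[0] += jitter[0]
            p[1] += jitter[1]
            p[2] -= s * thickness_mm
            radius = float("nan")
            if key[0] == "n":
                radius = float(neuron.radius_um[key[1]])
                node_type = int(neuron.types[key[1]])
            idx = b.add_node(parent_local, node_type, p, radius)
            local[key] = idx
            return idx

        # parent-first: iterate until all pieces placed (handles ordering)
        pending = list(sec_pieces)
        # roots in this section: keys whose parent-side piece is elsewhere
        child_keys = {p[2] for p in sec_pieces}
        for p in sec_pieces:
            if p[1] not in child_keys and p[1] not in local:
                localize(p[1], p[4], ROOT_PARENT, p[3])
        if not sec_pieces and s == sections_present[0]:
            localize(root_key, neuron.xyz[neuron.root_indices[0]].copy(),
                     ROOT_PARENT, int(neuron.types[neuron.root_indices[0]]))
        guard = 0
        while pending:
            guard += 1
            if guard > len(pieces) * len(pieces) + 10:
                raise RuntimeError("sectioning failed to order fragments")
            rest = []
            for p in pending:
                if p[1] in local:
                    localize(p[2], p[5], local[p[1]], p[3])
                else:
                    rest.append(p)
            pending = rest

        sections.append(
            Section(
                index=s,
                fragment=b.build(strict=False),
                shift_ml=-float(jitter[0]),
                shift_ap=-float(jitter[1]),
            )
        )

    return SectionStack(
        sections,
        thickness_mm,
        neuron_id=neuron.neuron_id,
        frame=neuron.frame,
    )


# --------------------------------------------------------------------------- #
# bulk-labeling density volumes
# --------------------------------------------------------------------------- #
@dataclass
class BulkDensityResult:
    volumes: list[DensityVolume]
    planted_centers: dict[str, np.ndarray]  # region -> (n_animals, 2) bregma mm
    sites: list[InjectionSite]


def generate_bulk_density(
    n_animals: int = 5,
    centers=None,
    model: RegionModel | None = None,
    grid: GridSpec | None = None,
    blob_sigma_mm: float = 0.05,
    mass_mm: float = 10.0,
    site_mean: tuple[float, float] = DEFAULT_INJECTION_SITE,
    site_sd: tuple[float, float] = (0.06, 0.07),
    seed: int = 0,
) -> BulkDensityResult:
    """Simulate per-animal axon-density volumes with Gaussian hotspots.

    Per animal, the injection site is drawn around ``site_mean`` and each
    region's hotspot centre is site + N(offset mean, offset SD) using the
    packaged projection-centre table (or ``centers`` in the same format).
    Each hotspot is an isotropic 3D Gaussian blob of ``mass_mm`` of cable
    centred at the drawn (ml, ap) and mid-way through the region's dv band.
    Returns the volumes together with the planted centres for recovery tests.
    """
    centers = centers or DEFAULT_PROJECTION_CENTERS
    model = model or default_region_model()
    grid = grid or GridSpec()
    rng = np.random.default_rng(seed)

    volumes: list[DensityVolume] = []
    planted: dict[str, list[np.ndarray]] = {r: [] for r in centers}
    sites: list[InjectionSite] = []
    for _ in range(n_animals):
        site = np.asarray(site_mean) + rng.normal(0.0, site_sd)
        sites.append(InjectionSite(float(site[0]), float(site[1])))
        vol = grid.empty_volume()
        for name, entry in centers.items():
            mass = entry.get("mass_mm", mass_mm)
            if mass <= 0:
                warnings.warn(f"region {name!r}: zero hotspot mass, skipped",
                              stacklevel=2)
                continue
            offset = np.asarray(entry["offset"], float) + rng.normal(
                0.0, np.asarray(entry["offset_sd"], float)
            )
            c_mlap = site + offset
            region = model[name]
            c_dv = (region.dv_min + region.dv_max) / 2.0
            _add_gaussian_blob(
                vol, (c_mlap[0], c_mlap[1], c_dv), blob_sigma_mm, mass
            )
            planted[name].append(c_mlap)
        volumes.append(vol)
    return BulkDensityResult(
        volumes,
        {r: np.array(v) for r, v in planted.items() if v},
        sites,
    )


def _add_gaussian_blob(
    vol: DensityVolume, center, sigma_mm: float, mass_mm: float
) -> None:
    """Deposit an isotropic Gaussian blob, renormalized to exactly ``mass_mm``."""
    gs = [
        np.exp(-0.5 * ((vol.axis_centers(ax) - center[ax]) / sigma_mm) ** 2)
        for ax in range(3)
    ]
    blob = np.einsum("i,j,k->ijk", *gs)
    s = blob.sum()
    if s <= 0:
        raise SpecError("Gaussian blob falls entirely outside the grid")
    vol.values += blob * (mass_mm / s)
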