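"""Bregma-referenced region model and assignment of points/cable to regions.

The model describes each projection target of the wS1 (whisker primary
somatosensory, "barrel") cortex L2/3 system as a named axis-aligned domain in
a bregma-referenced frame:

* ``cortical_column`` — a box spanning the cortical depth (dv band),
* ``box`` — an arbitrary box (used for the dorsolateral striatum).

Sign conventions: ml negative = left hemisphere (the default model describes
a left-hemisphere injection), ap positive = anterior to Bregma, dv = depth
below the pia, positive down. Overlapping regions are resolved by an explicit
integer priority (smaller wins); wS1 carries the lowest priority among the
cortical regions so that the dysgranular subregions (AM/CM/PM) and wS2 win
where they abut the barrel field. Points contained in no region are labelled
``"elsewhere"`` (this includes all contralateral, ml > 0, territory).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import FrameError

ELSEWHERE = "elsewhere"

#: canonical target-region order used by reports and matrices
CANONICAL_REGION_ORDER = (
    "wS1", "wS2", "wM1/2", "PL1", "PL2", "AM", "CM", "PM", "PP", "TeA",
    "Striatum",
)

#: default injection site: centre of the C2 barrel column, left wS1 (mm, bregma)
DEFAULT_INJECTION_SITE = (-3.02, -1.65)

#: Estimated projection-hotspot centres for the wS1 L2/3 system (mm).
#: ``offset`` columns are relative to the wS1 injection site, ``bregma``
#: columns relative to Bregma; ``*_sd`` are across-animal SDs (n = 5 mice).
DEFAULT_PROJECTION_CENTERS: dict[str, dict[str, tuple[float, float]]] = {
    "wS1":      {"offset": (0.00, 0.00),   "offset_sd": (0.00, 0.00),
                 "bregma": (-3.02, -1.65), "bregma_sd": (0.06, 0.07)},
    "wS2":      {"offset": (-0.82, 0.02),  "offset_sd": (0.06, 0.05),
                 "bregma": (-3.83, -1.63), "bregma_sd": (0.06, 0.11)},
    "wM1/2":    {"offset": (2.21, 2.70),   "offset_sd": (0.12, 0.09),
                 "bregma": (-0.81, 1.04),  "bregma_sd": (0.09, 0.09)},
    "PL1":      {"offset": (-1.12, -0.36), "offset_sd": (0.06, 0.00),
                 "bregma": (-4.13, -2.01), "bregma_sd": (0.09, 0.07)},
    "PL2":      {"offset": (-0.66, -0.36), "offset_sd": (0.07, 0.00),
                 "bregma": (-3.67, -2.01), "bregma_sd": (0.08, 0.07)},
    "AM":       {"offset": (0.48, 0.93),   "offset_sd": (0.09, 0.31),
                 "bregma": (-2.54, -0.72), "bregma_sd": (0.05, 0.35)},
    "CM":       {"offset": (0.70, 0.19),   "offset_sd": (0.10, 0.14),
                 "bregma": (-2.32, -1.46), "bregma_sd": (0.09, 0.12)},
    "PM":       {"offset": (0.51, -0.38),  "offset_sd": (0.06, 0.05),
                 "bregma": (-2.51, -2.04), "bregma_sd": (0.10, 0.05)},
    "PP":       {"offset": (-0.49, -1.49), "offset_sd": (0.04, 0.22),
                 "bregma": (-3.51, -3.14), "bregma_sd": (0.03, 0.25)},
    "TeA":      {"offset": (-1.43, -0.36), "offset_sd": (0.04, 0.00),
                 "bregma": (-4.45, -2.01), "bregma_sd": (0.06, 0.07)},
    "Striatum": {"offset": (0.18, 0.29),   "offset_sd": (0.14, 0.07),
                 "bregma": (-2.83, -1.36), "bregma_sd": (0.12, 0.10)},
}

#: dv band (mm below pia) spanned by cortical columns in the default model
CORTICAL_DV_RANGE = (0.0, 1.2)
#: dv band of the dorsolateral striatum box in the default model
STRIATUM_DV_RANGE = (1.5, 3.5)


# --------------------------------------------------------------------------- #
# frame transforms
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class InjectionSite:
    """Bregma-frame (ml, ap) of the tracer/virus injection site (mm)."""

    bregma_ml: float = DEFAULT_INJECTION_SITE[0]
    bregma_ap: float = DEFAULT_INJECTION_SITE[1]

    @property
    def mlap(self) -> np.ndarray:
        return np.array([self.bregma_ml, self.bregma_ap])


def injection_to_bregma(offset_mlap, site: InjectionSite) -> np.ndarray:
    """Convert injection-site-relative (ml, ap) offsets to the bregma frame.

    The two frames differ by a pure translation: ``bregma = site + offset``.
    Accepts a single pair or an (n, 2) array.
    """
    offset = np.asarray(offset_mlap, dtype=float)
    if not np.all(np.isfinite(offset)):
        raise ValueError("non-finite offset coordinates")
    return offset + site.mlap


def bregma_to_injection(bregma_mlap, site: InjectionSite) -> np.ndarray:
    """Inverse of :func:`injection_to_bregma`: ``offset = bregma - site``."""
    bregma = np.asarray(bregma_mlap, dtype=float)
    if not np.all(np.isfinite(bregma)):
        raise ValueError("non-finite bregma coordinates")
    return bregma - site.mlap


# --------------------------------------------------------------------------- #
# region model
# --------------------------------------------------------------------------- #
@dataclass(frozen=True)
class RegionDef:
    """One named axis-aligned region (all coordinates mm, bregma frame)."""

    name: str
    shape: str  # "cortical_column" | "box"
    center_ml: float
    center_ap: float
    half_ml: float
    half_ap: float
    dv_min: float
    dv_max: float
    priority: int

    def __post_init__(self) -> None:
        if self.name == ELSEWHERE:
            raise ValueError(f"region name {ELSEWHERE!r} is reserved")
        if self.shape not in ("cortical_column", "box"):
            raise ValueError(f"unknown region shape {self.shape!r}")
        if self.half_ml <= 0 or self.half_ap <= 0:
            raise ValueError(f"{self.name}: half extents must be positive")
        if not self.dv_min < self.dv_max:
            raise ValueError(f"{self.name}: requires dv_min < dv_max")

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min, max] per axis (ml, ap, dv)."""
        return np.array(
            [
                [self.center_ml - self.half_ml, self.center_ap - self.half_ap,
                 self.dv_min],
                [self.center_ml + self.half_ml, self.center_ap + self.half_ap,
                 self.dv_max],
            ]
        )

    def contains(self, points) -> np.ndarray:
        """Boundary-inclusive containment test for (n, 3) points (mm)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        lo, hi = self.bounds
        return np.all((p >= lo) & (p <= hi), axis=1)


@dataclass
class RegionModel:
    """Ordered collection of regions plus the injection site."""

    regions: list[RegionDef]
    injection_site: InjectionSite = field(default_factory=InjectionSite)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ValueError("region names must be unique")
        # evaluation order = ascending priority, ties broken by listed order
        self._ordered = sorted(
            range(len(self.regions)), key=lambda i: (self.regions[i].priority, i)
        )

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def __getitem__(self, name: str) -> RegionDef:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)

    def by_priority(self) -> list[RegionDef]:
        return [self.regions[i] for i in self._ordered]

    def translated(self, delta_mlap) -> "RegionModel":
        """Shift all region centres and the injection site in ml/ap (mm)."""
        dml, dap = (float(c) for c in delta_mlap)
        moved = [
            RegionDef(
                **{
                    **asdict(r),
                    "center_ml": r.center_ml + dml,
                    "center_ap": r.center_ap + dap,
                }
            )
            for r in self.regions
        ]
        site = InjectionSite(
            self.injection_site.bregma_ml + dml,
            self.injection_site.bregma_ap + dap,
        )
        return RegionModel(moved, site)


def default_region_model(injection_site: InjectionSite | None = None) -> RegionModel:
    """The packaged default model for the wS1 L2/3 projection system.

    Cortical columns are boxes centred on the default hotspot coordinates
    with 0.4 mm half-extents, except: wS1 is sized to the barrel field
    (1.0 x 1.0 mm), wM1/2 is elongated antero-posteriorly (the projection
    spans roughly 0.4-2.0 mm anterior to Bregma) and TeA is elongated
    antero-posteriorly (roughly 1.5-2.2 mm posterior). The striatum is a
    subcortical box spanning roughly 0.3-1.7 mm posterior to Bregma at
    1.5-3.5 mm depth. The published estimates locate hotspot *centres*, not
    boundaries, so all extents are explicit model choices and configurable.
    """
    site = injection_site or InjectionSite()
    c = {k: v["bregma"] for k, v in DEFAULT_PROJECTION_CENTERS.items()}
    dv0, dv1 = CORTICAL_DV_RANGE

    def col(name, half_ml=0.4, half_ap=0.4, priority=10):
        return RegionDef(
            name, "cortical_column", c[name][0], c[name][1],
            half_ml, half_ap, dv0, dv1, priority,
        )

    regions = [
        col("wS2", priority=0),
        col("wM1/2", half_ap=0.85, priority=1),
        col("TeA", half_ap=0.35, priority=2),
        col("PL1", priority=3),
        col("PL2", priority=4),
        col("PP", priority=5),
        col("AM", priority=6),
        col("CM", priority=7),
        col("PM", priority=8),
        RegionDef(
            "Striatum", "box", c["Striatum"][0], -1.0, 0.6, 0.7,
            STRIATUM_DV_RANGE[0], STRIATUM_DV_RANGE[1], 9,
        ),
        col("wS1", half_ml=1.0, half_ap=1.0, priority=100),
    ]
    return RegionModel(regions, site)


# --------------------------------------------------------------------------- #
# point and cable assignment
# --------------------------------------------------------------------------- #
def locate_points(points, model: RegionModel, frame: str = "bregma") -> list[str]:
    """Label each (ml, ap, dv) point with its highest-priority containing region."""
    if frame != "bregma":
        raise FrameError(f"points must be in the bregma frame, got {frame!r}")
    p = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.full(len(p), ELSEWHERE, dtype=object)
    unassigned = np.ones(len(p), dtype=bool)
    for r in model.by_priority():
        if not unassigned.any():
            break
        hit = unassigned & r.contains(p)
        labels[hit] = r.name
        unassigned &= ~hit
    return list(labels)


def locate_point(point, model: RegionModel, frame: str = "bregma") -> str:
    """Region name containing one point, or ``"elsewhere"``."""
    return locate_points([point], model, frame)[0]


def _crossing_parameters(p0: np.ndarray, p1: np.ndarray, model: RegionModel) -> np.ndarray:
    """Sorted parameters t in (0, 1) where segment p0->p1 crosses a region face."""
    d = p1 - p0
    ts: list[float] = []
    for r in model.regions:
        lo, hi = r.bounds
        for axis in range(3):
            if d[axis] == 0.0:
                continue
            for plane in (lo[axis], hi[axis]):
                t = (plane - p0[axis]) / d[axis]
                if 0.0 < t < 1.0:
                    ts.append(t)
    if not ts:
        return np.empty(0)
    return np.unique(ts)


def clip_polyline_to_regions(
    chain, model: RegionModel, frame: str = "bregma"
) -> dict[str, float]:
    """Partition a polyline's cable length (mm) among regions.

    Every edge is split analytically at region-face crossings and each
    sub-segment accrues to the region containing its midpoint (priority
    rules as in :func:`locate_point`). The returned lengths sum to the total
    chain length to ~1e-12 relative (the split parameters telescope).
    """
    pts = np.atleast_2d(np.asarray(chain, dtype=float))
    if len(pts) < 2:
        raise ValueError("polyline needs at least 2 points")
    if frame != "bregma":
        raise FrameError(f"chain must be in the bregma frame, got {frame!r}")
    out: dict[str, float] = {}
    for p0, p1 in zip(pts[:-1], pts[1:]):
        seg_len = float(np.linalg.norm(p1 - p0))
        if seg_len == 0.0:
            continue
        ts = np.concatenate([[0.0], _crossing_parameters(p0, p1, model), [1.0]])
        mids = p0 + np.outer((ts[:-1] + ts[1:]) / 2.0, p1 - p0)
        labels = locate_points(mids, model)
        pieces = seg_len * np.diff(ts)
        for lab, piece in zip(labels, pieces):
            out[lab] = out.get(lab, 0.0) + float(piece)
    return out


# --------------------------------------------------------------------------- #
# interior boxes (used by the synthetic generator to plant cable)
# --------------------------------------------------------------------------- #
def effective_interior_box(
    model: RegionModel,
    name: str,
    margin: float = 0.05,
    containing: tuple[float, float] | None = None,
) -> np.ndarray:
    """Largest-area axis-aligned ml/ap box strictly inside region ``name``.

    The box is shrunk by ``margin`` from the region's own faces and avoids
    every *higher-priority* region (dilated by ``margin``) whose dv band
    overlaps, so that any cable planted inside it is assigned to ``name``
    with at least ``margin`` clearance. When ``containing`` is given, only
    candidate boxes containing that (ml, ap) point are considered. Returns
    (2, 3) [min, max] bounds (the dv band is the region's own, shrunk by
    ``margin``).
    """
    region = model[name]
    lo, hi = region.bounds
    base = np.array(
        [[lo[0] + margin, lo[1] + margin], [hi[0] - margin, hi[1] - margin]]
    )
    if np.any(base[0] >= base[1]):
        raise ValueError(f"{name}: margin {margin} leaves no interior")

    obstacles = []
    for other in model.by_priority():
        if other.name == name:
            break  # only regions that would win over `name` matter
        olo, ohi = other.bounds
        if ohi[2] <= lo[2] or olo[2] >= hi[2]:
            continue  # disjoint dv bands
        ob = np.array(
            [[olo[0] - margin, olo[1] - margin], [ohi[0] + margin, ohi[1] + margin]]
        )
        # clip to base; skip if no overlap
        if (ob[1][0] <= base[0][0] or ob[0][0] >= base[1][0]
                or ob[1][1] <= base[0][1] or ob[0][1] >= base[1][1]):
            continue
        obstacles.append(ob)

    dv_band = (lo[2] + margin, hi[2] - margin)

    def as_bounds(x0, x1, y0, y1):
        return np.array(
            [[x0, y0, dv_band[0]], [x1, y1, dv_band[1]]]
        )

    def admits(x0, x1, y0, y1) -> bool:
        if containing is None:
            return True
        return x0 <= containing[0] <= x1 and y0 <= containing[1] <= y1

    if not obstacles:
        if not admits(base[0][0], base[1][0], base[0][1], base[1][1]):
            raise ValueError(
                f"{name}: requested point {containing} is not interior"
            )
        return as_bounds(base[0][0], base[1][0], base[0][1], base[1][1])

    # candidate grid lines from base and obstacle edges
    xs = sorted({base[0][0], base[1][0], *(o[0][0] for o in obstacles),
                 *(o[1][0] for o in obstacles)})
    ys = sorted({base[0][1], base[1][1], *(o[0][1] for o in obstacles),
                 *(o[1][1] for o in obstacles)})
    xs = [x for x in xs if base[0][0] <= x <= base[1][0]]
    ys = [y for y in ys if base[0][1] <= y <= base[1][1]]

    best, best_area = None, 0.0
    for (x0, x1), (y0, y1) in itertools.product(
        itertools.combinations(xs, 2), itertools.combinations(ys, 2)
    ):
        area = (x1 - x0) * (y1 - y0)
        if area <= best_area or not admits(x0, x1, y0, y1):
            continue
        free = all(
            o[1][0] <= x0 or o[0][0] >= x1 or o[1][1] <= y0 or o[0][1] >= y1
            for o in obstacles
        )
        if free:
            best, best_area = (x0, x1, y0, y1), area
    if best is None:
        raise ValueError(
            f"{name}: higher-priority regions leave no admissible interior "
            f"space{' containing ' + str(containing) if containing else ''}"
        )
    return as_bounds(*best)


# --------------------------------------------------------------------------- #
# config I/O
# --------------------------------------------------------------------------- #
_CONFIG_COLUMNS = [
    "name", "shape", "center_ml", "center_ap", "half_ml", "half_ap",
    "dv_min", "dv_max", "priority",
]


def write_region_model(model: RegionModel, path) -> Path:
    """Write a region model as a CSV config (one row per region + site row)."""
    path = Path(path)
    rows = [asdict(r) for r in model.regions]
    df = pd.DataFrame(rows)[_CONFIG_COLUMNS]
    site = model.injection_site
    with open(path, "w") as fh:
        fh.write(f"# injection_site_ml={site.bregma_ml} "
                 f"injection_site_ap={site.bregma_ap}\n")
        df.to_csv(fh, index=False)
    return path


def read_region_model(path) -> RegionModel:
    """Read a region model CSV written by :func:`write_region_model`."""
    path = Path(path)
    site = InjectionSite()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            parts = dict(
                kv.split("=") for kv in first.lstrip("# ").split() if "=" in kv
            )
            site = InjectionSite(
                float(parts.get("injection_site_ml", DEFAULT_INJECTION_SITE[0])),
                float(parts.get("injection_site_ap", DEFAULT_INJECTION_SITE[1])),
            )
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    missing = set(_CONFIG_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"region config missing columns: {sorted(missing)}")
    regions = [
        RegionDef(**{k: row[k] for k in _CONFIG_COLUMNS})
        for _, row in df.astype({"priority": int}).iterrows()
    ]
    return RegionModel(regions, site)
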