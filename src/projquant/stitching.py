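"""Assembly of per-section tracing fragments into one 3D reconstruction.

Serial sectioning cuts neurites at section faces; tracing yields, per
section, a forest of neurite pieces in section-local coordinates (dv within
[0, thickness]). Stitching places section k at a dv offset of k x thickness,
applies the manifest's rigid in-plane translation (no rotation or scaling),
and re-joins cut endpoints: every fragment root that is not the soma is
attached to its nearest node in an adjacent section, provided that node lies
within the merge tolerance (default 5 µm). Coincident endpoints (< 1 nm) are
collapsed rather than joined with a zero-length edge.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .morphology import (
    ROOT_PARENT,
    SOMA,
    MorphologyError,
    NeuronReconstruction,
)
from . import swc as swc_io

#: endpoints closer than this are the same physical point (mm)
COLLAPSE_EPS_MM = 1e-9


@dataclass
class Section:
    """One physical section: index in the stack, fragment, in-plane shift.

    ``shift_ml/ap`` is the rigid translation (mm) applied to the fragment
    when stitching (e.g. the inverse of the mounting offset).
    """

    index: int
    fragment: NeuronReconstruction
    shift_ml: float = 0.0
    shift_ap: float = 0.0


@dataclass
class SectionStack:
    """Ordered serial sections plus the cutting thickness (mm)."""

    sections: list[Section]
    section_thickness_mm: float
    neuron_id: str = "stitched"
    frame: str = "bregma"

    def __post_init__(self) -> None:
        if self.section_thickness_mm <= 0:
            raise ValueError("section thickness must be positive")
        idx = [s.index for s in self.sections]
        if sorted(idx) != idx or len(set(idx)) != len(idx):
            raise ValueError("section indices must be strictly increasing")


class StitchError(MorphologyError):
    """Stitching failed; carries the offending endpoint report."""

    def __init__(self, message: str, unmerged=None, candidates=None):
        super().__init__(message)
        self.unmerged = unmerged or []
        self.candidates = candidates or []


def stitch_sections(
    stack: SectionStack, tolerance_um: float = 5.0
) -> NeuronReconstruction:
    """Assemble a :class:`SectionStack` into a single valid reconstruction.

    Raises
    ------
    StitchError
        If any cut endpoint has no merge partner within ``tolerance_um``
        (the report lists them), or if two partners are exactly equidistant.
    MorphologyError
        If the merged graph is not a single rooted tree.
    """
    tol_mm = tolerance_um * 1e-3
    t = stack.section_thickness_mm

    # place fragments into the global frame
    xyz_parts, type_parts, rad_parts, parent_parts, sec_of = [], [], [], [], []
    offset = 0
    for sec in stack.sections:
        f = sec.fragment
        shifted = f.xyz + np.array([sec.shift_ml, sec.shift_ap, sec.index * t])
        xyz_parts.append(shifted)
        type_parts.append(f.types)
        rad_parts.append(f.radius_um)
        p = f.parent_index.copy()
        nonroot = p != ROOT_PARENT
        p[nonroot] += offset
        parent_parts.append(p)
        sec_of.append(np.full(f.n_nodes, sec.index))
        offset += f.n_nodes

    xyz = np.concatenate(xyz_parts)
    types = np.concatenate(type_parts)
    radius = np.concatenate(rad_parts)
    parent = np.concatenate(parent_parts)
    section_of = np.concatenate(sec_of)
    n = len(xyz)

    roots = np.flatnonzero(parent == ROOT_PARENT)
    soma_roots = roots[types[roots] == SOMA]
    if len(soma_roots) > 1:
        raise StitchError(
            f"{stack.neuron_id}: {len(soma_roots)} soma roots across sections"
        )
    true_root = int(soma_roots[0]) if len(soma_roots) else int(roots[0])

    # match every cut root to its nearest node in an adjacent section
    collapse_into: dict[int, int] = {}
    unmerged: list[dict] = []
    for r in roots:
        if r == true_root:
            continue
        neighbour = np.abs(section_of - section_of[r]) == 1
        cand = np.flatnonzero(neighbour)
        if len(cand) == 0:
            unmerged.append(_endpoint_report(r, section_of[r], xyz[r]))
            continue
        d = np.linalg.norm(xyz[cand] - xyz[r], axis=1)
        within = cand[d <= tol_mm]
        dw = d[d <= tol_mm]
        if len(within) == 0:
            unmerged.append(_endpoint_report(r, section_of[r], xyz[r]))
            continue
        order = np.argsort(dw)
        if len(within) > 1 and abs(dw[order[0]] - dw[order[1]]) < 1e-12:
            tied = within[order[:2]]
            raise StitchError(
                f"{stack.neuron_id}: ambiguous merge for endpoint at "
                f"{np.round(xyz[r], 6)} (section {section_of[r]}): candidates "
                f"at {np.round(xyz[tied[0]], 6)} and {np.round(xyz[tied[1]], 6)} "
                "are exactly equidistant",
                candidates=[int(i) for i in tied],
            )
        partner = int(within[order[0]])
        if dw[order[0]] < COLLAPSE_EPS_MM:
            collapse_into[int(r)] = partner
        parent[r] = partner

    if unmerged:
        report = "; ".join(
            f"section {u['section']} at {u['position_mm']}" for u in unmerged
        )
        raise StitchError(
            f"{stack.neuron_id}: {len(unmerged)} cut endpoint(s) without a "
            f"merge partner within {tolerance_um} µm: {report}",
            unmerged=unmerged,
        )

    # resolve collapse chains (a root merged onto a node that itself collapses)
    def resolve(i: int) -> int:
        seen = set()
        while i in collapse_into:
            if i in seen:
                raise MorphologyError(f"{stack.neuron_id}: collapse cycle")
            seen.add(i)
            i = collapse_into[i]
        return i

    keep = np.ones(n, dtype=bool)
    for dup in collapse_into:
        keep[dup] = False
    final_parent = parent.copy()
    for i in range(n):
        if final_parent[i] != ROOT_PARENT:
            final_parent[i] = resolve(int(final_parent[i]))

    # breadth-first re-order from the root; detects cycles and disconnection
    children: dict[int, list[int]] = {}
    for i in range(n):
        if keep[i] and final_parent[i] != ROOT_PARENT:
            children.setdefault(int(final_parent[i]), []).append(i)
    order: list[int] = []
    stack_idx = [resolve(true_root)]
    seen = set()
    while stack_idx:
        i = stack_idx.pop()
        if i in seen:
            raise MorphologyError(f"{stack.neuron_id}: cycle after merging")
        seen.add(i)
        order.append(i)
        stack_idx.extend(reversed(children.get(i, [])))
    if len(order) != int(keep.sum()):
        raise MorphologyError(
            f"{stack.neuron_id}: stitched graph is not connected "
            f"({len(order)} of {int(keep.sum())} nodes reachable from the root)"
        )

    new_index = {old: k for k, old in enumerate(order)}
    return NeuronReconstruction(
        neuron_id=stack.neuron_id,
        ids=np.arange(1, len(order) + 1),
        parent_index=np.array(
            [
                ROOT_PARENT
                if final_parent[i] == ROOT_PARENT
                else new_index[int(final_parent[i])]
                for i in order
            ]
        ),
        types=types[order],
        xyz=xyz[order],
        radius_um=radius[order],
        frame=stack.frame,
        provenance={
            "stitched_from_sections": [s.index for s in stack.sections],
            "section_thickness_mm": t,
            "tolerance_um": tolerance_um,
        },
    )


def _endpoint_report(node: int, section: int, pos: np.ndarray) -> dict:
    return {
        "node": int(node),
        "section": int(section),
        "position_mm": [round(float(c), 6) for c in pos],
    }


# --------------------------------------------------------------------------- #
# manifest I/O
# --------------------------------------------------------------------------- #
def write_section_stack(stack: SectionStack, out_dir) -> Path:
    """Write per-section SWC fragments plus a CSV stitching manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sec in stack.sections:
        fname = f"{stack.neuron_id}_s{sec.index:03d}.swc"
        swc_io.write_swc(sec.fragment, out_dir / fname)
        rows.append(
            {
                "section_index": sec.index,
                "filename": fname,
                "shift_ml_mm": sec.shift_ml,
                "shift_ap_mm": sec.shift_ap,
            }
        )
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w") as fh:
        fh.write(f"# section_thickness_mm={stack.section_thickness_mm} "
                 f"neuron_id={stack.neuron_id}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)
    return manifest


def read_section_stack(
    manifest_path, section_thickness_mm: float | None = None
) -> SectionStack:
    """Read a stitching manifest (CSV; fragment paths relative to it)."""
    manifest_path = Path(manifest_path)
    neuron_id = "stitched"
    header_thickness = None
    with open(manifest_path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            parts = dict(
                kv.split("=") for kv in first.lstrip("# ").split() if "=" in kv
            )
            header_thickness = float(parts.get("section_thickness_mm", "nan"))
            neuron_id = parts.get("neuron_id", neuron_id)
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    thickness = section_thickness_mm or header_thickness
    if thickness is None or not np.isfinite(thickness):
        raise ValueError("section thickness missing from manifest and arguments")
    sections = [
        Section(
            index=int(row.section_index),
            fragment=swc_io.read_swc(
                manifest_path.parent / row.filename, strict=False,
                frame="section-local",
            ),
            shift_ml=float(row.shift_ml_mm),
            shift_ap=float(row.shift_ap_mm),
        )
        for row in df.sort_values("section_index").itertuples()
    ]
    return SectionStack(sections, thickness, neuron_id=neuron_id)
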