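"""Reading and writing reconstructions in the 7-column SWC text format.

Each body line is ``id type x y z radius parent``. Comment lines start with
``#``. Coordinates are interpreted in the unit declared by a header comment
``# UNITS um|mm`` or by the ``unit`` argument (micrometres by default, the
common convention for deposited reconstructions) and converted to millimetres
internally. SWC axes map to the anatomical frame as x=ml, y=ap, z=dv.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .morphology import ROOT_PARENT, MorphologyError, NeuronReconstruction

#: radius written when a reconstruction has no radius information (µm)
DEFAULT_RADIUS_UM = 1.0

_UNIT_SCALE_TO_MM = {"um": 1e-3, "micron": 1e-3, "microns": 1e-3, "mm": 1.0}
_UNITS_RE = re.compile(r"#\s*UNITS?\s*[:=]?\s*([a-zA-Z]+)", re.IGNORECASE)
_FRAME_RE = re.compile(r"#\s*FRAME\s*[:=]?\s*([a-zA-Z-]+)", re.IGNORECASE)


class SwcParseError(ValueError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


def read_swc(
    path,
    neuron_id: str | None = None,
    unit: str | None = None,
    frame: str | None = None,
    strict: bool = True,
) -> NeuronReconstruction:
    """Parse an SWC file into a :class:`NeuronReconstruction` (mm internally).

    Parameters
    ----------
    path
        SWC file to read.
    unit
        Coordinate unit override (``"um"`` or ``"mm"``). When omitted, a
        ``# UNITS`` header comment is honoured, else micrometres are assumed.
    frame
        Anatomical frame tag override; a ``# FRAME`` header comment is
        honoured, else ``"bregma"``.
    strict
        Enforce single-tree invariants (set False for section fragments).
    """
    path = Path(path)
    text = path.read_text()
    header_unit = None
    header_frame = None

    ids: list[int] = []
    types: list[int] = []
    xyz: list[tuple[float, float, float]] = []
    radius: list[float] = []
    parent_ids: list[int] = []

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = _UNITS_RE.match(line)
            if m:
                header_unit = m.group(1).lower()
            m = _FRAME_RE.match(line)
            if m:
                header_frame = m.group(1).lower()
            continue
        fields = line.split()
        if len(fields) != 7:
            raise SwcParseError(
                f"expected 7 whitespace-delimited columns, got {len(fields)}",
                lineno,
            )
        try:
            ids.append(int(fields[0]))
            types.append(int(fields[1]))
            xyz.append((float(fields[2]), float(fields[3]), float(fields[4])))
            radius.append(float(fields[5]))
            parent_ids.append(int(fields[6]))
        except ValueError as exc:
            raise SwcParseError(str(exc), lineno) from None

    unit_name = (unit or header_unit or "um").lower()
    if unit_name not in _UNIT_SCALE_TO_MM:
        raise ValueError(f"unknown coordinate unit {unit_name!r}")
    scale = _UNIT_SCALE_TO_MM[unit_name]

    id_arr = np.array(ids, dtype=np.int64)
    index_of = {int(i): k for k, i in enumerate(id_arr)}
    if len(index_of) != len(id_arr):
        uniq, counts = np.unique(id_arr, return_counts=True)
        raise MorphologyError(
            f"duplicate sample ids in {path.name}: {uniq[counts > 1][:5]}"
        )

    parent_index = np.empty(len(id_arr), dtype=np.int64)
    for k, pid in enumerate(parent_ids):
        if pid == ROOT_PARENT:
            parent_index[k] = ROOT_PARENT
        elif pid in index_of:
            parent_index[k] = index_of[pid]
        else:
            raise MorphologyError(
                f"{path.name}: node {ids[k]} references absent parent {pid}"
            )

    # the radius column shares the coordinate unit; store it in µm
    rad_um = np.array(radius, dtype=np.float64) * scale * 1e3
    return NeuronReconstruction(
        neuron_id=neuron_id or path.stem,
        ids=id_arr,
        parent_index=parent_index,
        types=np.array(types, dtype=np.int64),
        xyz=np.array(xyz, dtype=np.float64) * scale,
        radius_um=rad_um,
        frame=frame or header_frame or "bregma",
        provenance={"source": str(path), "unit": unit_name},
        strict=strict,
    )


def write_swc(neuron: NeuronReconstruction, path, unit: str = "um") -> Path:
    """Write a reconstruction as standard 7-column SWC.

    Coordinates are emitted in ``unit`` (µm by default) with full double
    precision so that ``read_swc(write_swc(n))`` is an identity on topology
    and coordinates. Missing radii are filled with the documented sentinel
    of 1.0 µm.
    """
    unit = unit.lower()
    if unit not in _UNIT_SCALE_TO_MM:
        raise ValueError(f"unknown coordinate unit {unit!r}")
    scale = 1.0 / _UNIT_SCALE_TO_MM[unit]

    path = Path(path)
    rad_um = np.where(np.isnan(neuron.radius_um), DEFAULT_RADIUS_UM, neuron.radius_um)
    rad = rad_um * (1e-3 if unit == "mm" else 1.0)
    lines = [
        f"# {neuron.neuron_id}",
        f"# UNITS {unit}",
        f"# FRAME {neuron.frame}",
        "# id type x(ml) y(ap) z(dv) radius parent",
    ]
    coords = neuron.xyz * scale
    for k in range(neuron.n_nodes):
        pk = neuron.parent_index[k]
        pid = ROOT_PARENT if pk == ROOT_PARENT else int(neuron.ids[pk])
        x, y, z = coords[k]
        lines.append(
            f"{int(neuron.ids[k])} {int(neuron.types[k])} "
            f"{x:.12g} {y:.12g} {z:.12g} {rad[k]:.12g} {pid}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path
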