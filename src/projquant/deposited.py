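"""End-to-end pipeline over a directory of deposited SWC reconstructions.

Runs morphometry, projection quantification, classification and group
statistics over every ``*.swc`` file in a directory, exactly as for the
synthetic cohorts. Deposited single-cell reconstructions are typically
distributed in Neurolucida formats and must be converted to SWC once,
externally, before use (Neurolucida import is deliberately out of scope).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .morphometry import summarize
from .projection import (
    classify_projection_class,
    core_fraction,
    group_summary,
    quantify_projection,
    threshold_matrix,
)
from .regions import RegionModel, default_region_model
from .swc import read_swc


def analyze_directory(
    data_dir,
    model: RegionModel | None = None,
    unit: str | None = None,
) -> dict:
    """Analyze every SWC reconstruction under ``data_dir``.

    Returns a dict with per-neuron ``summaries`` and ``profiles``, the
    thresholded ``matrix``, per-neuron ``labels`` (S2p/M1p by dominant
    target) and ``core_fractions``, and the per-group ``groups`` table.
    """
    data_dir = Path(data_dir)
    paths = sorted(data_dir.glob("*.swc"))
    if not paths:
        raise FileNotFoundError(f"no SWC files under {data_dir}")
    model = model or default_region_model()

    neurons = [read_swc(p, unit=unit) for p in paths]
    summaries = [summarize(n) for n in neurons]
    profiles = [quantify_projection(n, model) for n in neurons]
    labels = [classify_projection_class(p) for p in profiles]
    fractions = {p.neuron_id: core_fraction(p) for p in profiles}
    matrix = threshold_matrix(profiles, regions=model.names)
    groups = group_summary(profiles, summaries, labels)
    return {
        "summaries": summaries,
        "profiles": profiles,
        "labels": labels,
        "core_fractions": fractions,
        "matrix": matrix,
        "groups": groups,
    }


def reproduce_group_statistics(data_dir, model: RegionModel | None = None) -> pd.DataFrame:
    """Headline per-group statistics (mean ± SD) for a deposited dataset.

    Covers the standard report: dendritic length, stems, branch points,
    total axon, and per-region branching axon for the S2p and M1p groups.
    """
    return analyze_directory(data_dir, model)["groups"]
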