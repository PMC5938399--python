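#!/usr/bin/env python
"""Morphometry of the simulated cohort (dendrites, stems, nodes, total axon).

Reads the SWC files produced by 02_simulate_cohort.py (regenerating them if
absent), computes the per-neuron summary and the per-class mean ± SD, and
writes results/03_morphometry.csv and results/03_morphometry_groups.csv.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from projquant import read_swc, summarize

ROOT = Path(__file__).resolve().parent.parent
COHORT = ROOT / "results" / "cohort"


def main() -> None:
    if not COHORT.is_dir() or not list(COHORT.glob("*.swc")):
        subprocess.run(
            [sys.executable, str(ROOT / "analysis" / "02_simulate_cohort.py")],
            check=True,
        )
    truth = pd.read_csv(COHORT / "ground_truth.csv").set_index("neuron_id")
    rows = []
    for path in sorted(COHORT.glob("*.swc")):
        s = summarize(read_swc(path))
        rows.append({**s.as_dict(), "class": truth.loc[s.neuron_id, "class"]})
    df = pd.DataFrame(rows)
    groups = df.drop(columns="neuron_id").groupby("class") \
        .agg(["mean", lambda x: x.std(ddof=1)])
    groups.columns = [f"{m}_{'sd' if s == '<lambda_0>' else s}"
                      for m, s in groups.columns]

    df.to_csv(ROOT / "results" / "03_morphometry.csv", index=False)
    groups.to_csv(ROOT / "results" / "03_morphometry_groups.csv")
    print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
    print("\nPer-class mean ± SD:")
    for cls, g in groups.iterrows():
        print(
            f"  {cls}: dendrites {g['dendritic_length_mm_mean']:.1f} ± "
            f"{g['dendritic_length_mm_sd']:.1f} mm, "
            f"stems {g['n_stems_mean']:.1f} ± {g['n_stems_sd']:.1f}, "
            f"nodes {g['n_branch_points_mean']:.0f} ± "
            f"{g['n_branch_points_sd']:.0f}, "
            f"axon {g['axonal_length_mm_mean']:.1f} ± "
            f"{g['axonal_length_mm_sd']:.1f} mm"
        )


if __name__ == "__main__":
    main()
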