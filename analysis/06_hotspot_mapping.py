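#!/usr/bin/env python
"""Across-animal hotspot mapping on simulated bulk-labeling volumes.

Simulates 5 animals whose 11 projection hotspots are Gaussian blobs drawn
around the packaged centre table at its printed across-animal SDs, then runs
the full centre-estimation chain (depth-band collapse, peak detection,
shift-registered assignment, 50%-of-peak centroid) and aggregates the centres
as mean ± SD in both frames. Writes results/06_hotspot_centers.csv in the
conventional four-column layout plus the recovery error per region.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from projquant import aggregate_centers, generate_bulk_density, hotspot_table
from projquant.regions import default_region_model

ROOT = Path(__file__).resolve().parent.parent
SEED = 1


def main() -> None:
    model = default_region_model()
    res = generate_bulk_density(n_animals=5, model=model, seed=SEED)
    estimates = aggregate_centers(res.volumes, model)
    table = hotspot_table(estimates)
    table["recovery_error_mm"] = [
        float(np.abs(e.mean_bregma
                     - res.planted_centers[e.region].mean(axis=0)).max())
        for e in estimates
    ]
    (ROOT / "results").mkdir(exist_ok=True)
    table.to_csv(ROOT / "results" / "06_hotspot_centers.csv", index=False)
    print(table.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\nworst recovery error: {table.recovery_error_mm.max():.3f} mm "
          "(tolerance 0.05 mm)")


if __name__ == "__main__":
    main()
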