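#!/usr/bin/env python
"""Check the two coordinate frames of the projection-centre table.

The packaged table lists each hotspot centre both relative to the wS1
injection site and relative to Bregma. The two frames differ by a pure
translation (the injection-site coordinates), so adding the wS1 site to each
offset must reproduce the bregma-frame columns up to the rounding of the
printed means. Writes the comparison to results/01_frame_transforms.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from projquant import InjectionSite, injection_to_bregma
from projquant.regions import DEFAULT_PROJECTION_CENTERS

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    site = InjectionSite(-3.02, -1.65)
    rows = []
    for name, entry in DEFAULT_PROJECTION_CENTERS.items():
        computed = injection_to_bregma(entry["offset"], site)
        printed = np.asarray(entry["bregma"])
        rows.append(
            {
                "region": name,
                "offset_ml": entry["offset"][0],
                "offset_ap": entry["offset"][1],
                "computed_bregma_ml": computed[0],
                "computed_bregma_ap": computed[1],
                "printed_bregma_ml": printed[0],
                "printed_bregma_ap": printed[1],
                "abs_error_mm": float(np.abs(computed - printed).max()),
            }
        )
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "01_frame_transforms.csv", index=False)
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(
        f"\nLargest discrepancy: {df.abs_error_mm.max():.3f} mm "
        "(consistent with 0.01 mm rounding of the printed means)."
    )


if __name__ == "__main__":
    main()
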