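#!/usr/bin/env python
"""Annual peak abundance and timing from the fitted components.

Finds: C. finmarchicus peaks in May-June (bin 3) in every region; the
Cen. typicus peak sits in Nov-Dec (bin 6) except in the MAB, where the
era cross-tabulation places the mode in bin 6 before 1985 and bin 1
after — the generator's built-in phenology shift, recovered from the
fitted series.
"""

from pathlib import Path

import pandas as pd

from copetrend import phenology
from copetrend.structural import AbundanceSeries, split_periods, fit

DATA = Path("scratch/data")
OUT = Path("results")
SEED = 1
ERA_SPLIT = 1985


def main() -> None:
    tidy = pd.read_csv(DATA / "series.csv")
    all_peaks = []
    for (sp, reg), grp in tidy.groupby(["species", "region"]):
        s = AbundanceSeries(
            sp, reg,
            grp.rename(columns={"mean_abundance": "value"})[
                ["year", "bin", "value", "n_samples"]
            ].reset_index(drop=True),
        )
        for label, sub in split_periods(s):
            f = fit(sub, period_label=label, seed=SEED)
            all_peaks.append(phenology.annual_peaks(f))
    peaks = pd.concat(all_peaks, ignore_index=True)
    OUT.mkdir(exist_ok=True)
    peaks.to_csv(OUT / "peaks.csv", index=False)
    print("modal peak bin by era (split at", ERA_SPLIT, "):")
    rows = []
    for (sp, reg), grp in peaks.groupby(["species", "region"]):
        tab, modal = phenology.peak_shift_table(grp, ERA_SPLIT)
        rows.append({"species": sp, "region": reg, **{f"mode_{k}": v for k, v in modal.items()}})
        print(f"  {sp} {reg}: early mode bin {modal['early']}, late mode bin {modal['late']}")
    pd.DataFrame(rows).to_csv(OUT / "peak_modes.csv", index=False)


if __name__ == "__main__":
    main()
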