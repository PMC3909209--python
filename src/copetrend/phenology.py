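"""Annual peak abundance and timing from fitted series.

Peaks are read from the fitted (trend + seasonal) series, not the raw
observations, so years with missing bins still yield a peak.  A year is
the calendar year of its bins (Nov-Dec is bin 6 of its own year; no
wrap-around), and ties go to the earliest bin.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .structural import StructuralFit

__all__ = ["annual_peaks", "peak_shift_table"]


def annual_peaks(fit: StructuralFit, use_observed: bool = False) -> pd.DataFrame:
    """One peak record per calendar year of the fit.

    Columns: species, region, period, year, peak_bin, peak_value, partial.
    ``partial`` flags years with fewer than 6 fitted bins (period edges).
    Set ``use_observed`` to extract peaks from the raw observations instead
    (bins missing from the data are then ignored).
    """
    if not fit.converged:
        raise ValueError("refusing to extract peaks from a non-converged fit")
    d = fit.series.data
    vals = fit.series.values if use_observed else fit.fitted
    frame = pd.DataFrame({"year": d["year"], "bin": d["bin"], "v": vals})
    if use_observed:
        frame = frame[np.isfinite(frame["v"])]
    records = []
    for year, grp in frame.groupby("year"):
        if grp["v"].notna().sum() == 0:
            continue
        # idxmax returns the first maximal row: earliest-bin tie-break
        top = grp.loc[grp["v"].idxmax()]
        records.append(
            {
                "species": fit.series.species,
                "region": fit.series.region,
                "period": fit.period_label,
                "year": int(year),
                "peak_bin": int(top["bin"]),
                "peak_value": float(top["v"]),
                "partial": bool(len(grp) < 6),
            }
        )
    return pd.DataFrame(records)


def peak_shift_table(
    records: pd.DataFrame, era_split_year: int
) -> tuple[pd.DataFrame, dict]:
    """Cross-tabulate peak_bin by era around ``era_split_year``.

    Era "early" is years strictly before the split.  Returns the count
    table (rows: era, columns: bin 1..6) and the modal bin per era (ties
    to the earliest bin).  Each era must hold at least 3 years.
    """
    if records.empty:
        raise ValueError("no peak records")
    rec = records.copy()
    rec["era"] = np.where(rec["year"] < era_split_year, "early", "late")
    counts = rec.groupby("era")["year"].nunique()
    for era in ("early", "late"):
        if counts.get(era, 0) < 3:
            raise ValueError(f"era '{era}' has fewer than 3 years")
    tab = (
        pd.crosstab(rec["era"], rec["peak_bin"])
        .reindex(index=["early", "late"], fill_value=0)
        .reindex(columns=range(1, 7), fill_value=0)
    )
    modal = {era: int(tab.loc[era].idxmax()) for era in ("early", "late")}
    return tab, modal
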