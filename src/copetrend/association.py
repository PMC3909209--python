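"""Regressions among peak abundance, transport, GSNWI and temperature.

Ordinary least squares with Pearson correlation and the two-sided t-test
p-value (n - 2 degrees of freedom).  The suite crosses every species and
region (plus the pooled "entire" shelf) with each physical covariate at the
annual scale, and adds the GSNWI ~ alongshore-velocity regression at both
bi-monthly and annual scales.  Nothing is filtered by significance and no
multiple-testing correction is applied; the full table is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AssociationResult", "regress", "association_suite"]


@dataclass(frozen=True)
class AssociationResult:
    response: str
    covariate: str
    region: str
    timescale: str          # "bimonthly" or "annual"
    n: int
    slope: float
    intercept: float
    r: float
    r2: float
    p: float

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.r <= 1.0 + 1e-12:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("n must be >= 3")


def regress(
    y,
    x,
    response: str = "y",
    covariate: str = "x",
    region: str = "",
    timescale: str = "annual",
) -> AssociationResult:
    """OLS of ``y`` on ``x`` after dropping incomplete pairs."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance covariate")
    res = stats.linregress(x, y)
    return AssociationResult(
        response=response,
        covariate=covariate,
        region=region,
        timescale=timescale,
        n=int(len(x)),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        p=float(res.pvalue),
    )


def _annual_by_year(s: pd.Series) -> pd.Series:
    """Index a yearly series by integer year whatever the incoming index."""
    if isinstance(s.index, pd.DatetimeIndex):
        return s.groupby(s.index.year).mean()
    if isinstance(s.index, pd.MultiIndex):
        return s.groupby(level="year").mean()
    return s


def association_suite(
    peaks: pd.DataFrame,
    velocity_bimonthly: pd.Series,
    gsnwi_index,
    temperature_annual: dict[str, pd.Series],
    transport_annual: pd.Series | None = None,
    use_cumulative: bool = False,
) -> pd.DataFrame:
    """The full association table (Tables S1-S3 layout plus Fig 11 rows).

    ``peaks`` is the annual peak table (species, region, year, peak_value);
    regions are crossed with the pooled "entire" response (mean of regional
    peak values per year).  The annual covariate for the peak regressions
    is the annual mean of the bi-monthly series (or the annual cumulative
    sum when ``use_cumulative``).  Rows where a regression is impossible
    (too few overlapping years) are skipped with a note column rather than
    raising, except when *nothing* overlaps.
    """
    vel_annual = (
        transport_annual
        if (use_cumulative and transport_annual is not None)
        else _annual_by_year(velocity_bimonthly)
    )
    gs_index = gsnwi_index.index if hasattr(gsnwi_index, "index") and hasattr(gsnwi_index, "weights") else gsnwi_index
    gs_bim = (
        gsnwi_index.bimonthly_mean()
        if hasattr(gsnwi_index, "bimonthly_mean")
        else _to_bim(gs_index)
    )
    gs_annual = _annual_by_year(gs_bim)

    covariates = {"alongshore_velocity": vel_annual, "gsnwi": gs_annual}
    rows: list[AssociationResult] = []
    n_peak_rows = 0
    skipped = 0

    species_list = sorted(peaks["species"].unique())
    region_list = sorted(peaks["region"].unique())
    for sp in species_list:
        sub = peaks[peaks["species"] == sp]
        by_region = {
            reg: grp.set_index("year")["peak_value"]
            for reg, grp in sub.groupby("region")
        }
        entire = sub.groupby("year")["peak_value"].mean()
        responses = {**by_region, "entire": entire}
        for reg in [*region_list, "entire"]:
            yser = responses.get(reg)
            if yser is None:
                continue
            for cov_name, cov in covariates.items():
                rows_or = _try_regress(
                    yser, cov, f"peak_{sp}", cov_name, reg, "annual"
                )
                if rows_or is None:
                    skipped += 1
                else:
                    rows.append(rows_or)
                    n_peak_rows += 1
            if reg in temperature_annual:
                r = _try_regress(
                    yser, temperature_annual[reg], f"peak_{sp}",
                    "temperature", reg, "annual",
                )
                if r is None:
                    skipped += 1
                else:
                    rows.append(r)
                    n_peak_rows += 1
    if n_peak_rows == 0:
        raise ValueError(
            "no overlapping years between the peak responses and the covariates"
        )

    # GSNWI ~ alongshore velocity at both timescales
    common = pd.concat([gs_bim, velocity_bimonthly], axis=1, join="inner")
    common.columns = ["gsnwi", "vel"]
    common = common.dropna()
    if len(common) >= 3:
        rows.append(
            regress(
                common["gsnwi"], common["vel"],
                response="gsnwi", covariate="alongshore_velocity",
                region="path", timescale="bimonthly",
            )
        )
    ann = pd.concat([gs_annual, vel_annual], axis=1, join="inner").dropna()
    if len(ann) >= 3:
        rows.append(
            regress(
                ann.iloc[:, 0], ann.iloc[:, 1],
                response="gsnwi", covariate="alongshore_velocity",
                region="path", timescale="annual",
            )
        )
    if not rows:
        raise ValueError("no overlapping years between responses and covariates")
    return pd.DataFrame([asdict(r) for r in rows])


def _to_bim(s: pd.Series) -> pd.Series:
    idx = pd.DatetimeIndex(s.index)
    g = s.groupby([idx.year, (idx.month + 1) // 2]).mean()
    g.index.names = ["year", "bin"]
    return g


def _try_regress(yser: pd.Series, cov: pd.Series, *names):
    joined = pd.concat([yser, cov], axis=1, join="inner").dropna()
    if len(joined) < 3:
        return None
    try:
        return regress(joined.iloc[:, 0], joined.iloc[:, 1], *names)
    except ValueError:
        return None
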