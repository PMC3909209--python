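"""Physical forcing indices: alongshore transport and the GSNWI.

The transport index is the mean northward (meridional) geostrophic
velocity over a fixed cross-shelf path: on the grid row nearest the path
latitude, take the six 1/3-degree cells within 2 degrees of the coast,
discard the two nearest the coast (land contamination), and average the
remaining four.  The Gulf Stream North Wall Index (GSNWI) is a weighted
average of the six standardized north-wall latitude series, the weights
being first-principal-component loadings rescaled to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "path_velocity",
    "to_bimonthly",
    "annual_cumulative",
    "gsnwi",
    "GSNWISeries",
]


def path_velocity(
    grid: xr.Dataset,
    path_lat: float = 39.3,
    coastal_extent_deg: float = 2.0,
    component: str = "v",
    coast_side: str = "west",
    n_discard: int = 2,
) -> pd.Series:
    """Weekly alongshore velocity on the coastal path (cm/s, + = northward).

    The path row is the grid latitude nearest ``path_lat``; the coast is
    located from the land mask (NaN cells) on that row.  With a 1/3-degree
    grid the 2-degree extent spans 6 cells; the ``n_discard`` nearest the
    coast are dropped and the rest averaged per time step.
    """
    lat_idx = int(np.argmin(np.abs(grid["lat"].values - path_lat)))
    row = grid[component].isel(lat=lat_idx)
    lons = grid["lon"].values
    spacing = float(grid.attrs.get("grid_spacing_deg", np.diff(lons).mean()))
    n_cells = int(round(coastal_extent_deg / spacing))
    ocean = np.flatnonzero(np.isfinite(row.values).any(axis=0))
    if len(ocean) == 0:
        raise ValueError(f"no ocean cells on the row nearest {path_lat}N")
    # the path is geometric: n contiguous cells from the first ocean cell
    if coast_side == "west":
        path_cols = np.arange(ocean[0], min(ocean[0] + n_cells, len(lons)))
    else:
        path_cols = np.arange(ocean[-1], max(ocean[-1] - n_cells, -1), -1)
    if len(path_cols) < n_cells:
        raise ValueError(
            f"path needs {n_cells} cells within {coastal_extent_deg} deg of the "
            f"coast, found {len(path_cols)}"
        )
    kept = path_cols[n_discard:]
    vals = row.isel(lon=kept).values  # (time, n_kept)
    bad = ~np.isfinite(vals)
    if bad.all(axis=0).any():
        missing = [float(lons[c]) for c, allbad in zip(kept, bad.all(axis=0)) if allbad]
        raise ValueError(f"missing cells on the path at lon {missing}")
    out = pd.Series(
        np.nanmean(vals, axis=1), index=pd.DatetimeIndex(grid["time"].values),
        name="alongshore_cm_s",
    )
    out.attrs = {
        "path_lat": float(grid["lat"].values[lat_idx]),
        "n_cells_averaged": int(len(kept)),
        "lons_used": [float(lons[c]) for c in kept],
    }
    return out


def to_bimonthly(weekly: pd.Series) -> pd.Series:
    """Bi-monthly means of a weekly series; empty bins are NaN.

    A week on a bin boundary belongs to the bin of its timestamp's month.
    Indexed by (year, bin).
    """
    if weekly.empty:
        raise ValueError("empty series")
    idx = pd.DatetimeIndex(weekly.index)
    year = idx.year
    b = (idx.month + 1) // 2
    g = weekly.groupby([year, b]).mean()
    g.index.names = ["year", "bin"]
    full = pd.MultiIndex.from_product(
        [range(year.min(), year.max() + 1), range(1, 7)], names=["year", "bin"]
    )
    return g.reindex(full)


def annual_cumulative(series: pd.Series) -> pd.DataFrame:
    """Annual cumulative northward and southward components.

    Per year, north_sum = sum of positive values, south_sum = sum of
    negative values; the two add up to the plain annual sum.  Works on the
    weekly series (DatetimeIndex) or the bi-monthly one ((year, bin)
    MultiIndex).  Years with missing entries are flagged partial.
    """
    if isinstance(series.index, pd.DatetimeIndex):
        years = series.index.year
        expected = None
    else:
        years = series.index.get_level_values("year")
        expected = 6
    rows = []
    for year, grp in series.groupby(years):
        v = grp.to_numpy(dtype=float)
        ok = np.isfinite(v)
        partial = (expected is not None and len(v) < expected) or (~ok).any()
        rows.append(
            {
                "year": int(year),
                "north_sum": float(np.sum(np.clip(v[ok], 0, None))),
                "south_sum": float(np.sum(np.clip(v[ok], None, 0))),
                "partial": bool(partial),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class GSNWISeries:
    """PCA-weighted Gulf Stream North Wall Index and its weights."""

    index: pd.Series            # standardized, dimensionless
    weights: pd.Series          # per longitude, sum to 1
    explained_var: float        # fraction carried by PC1

    def annual_mean(self) -> pd.Series:
        return self.index.groupby(self.index.index.year).mean()

    def bimonthly_mean(self) -> pd.Series:
        idx = pd.DatetimeIndex(self.index.index)
        g = self.index.groupby([idx.year, (idx.month + 1) // 2]).mean()
        g.index.names = ["year", "bin"]
        return g


def gsnwi(northwall: pd.DataFrame, min_months: int = 24) -> GSNWISeries:
    """Build the GSNWI from the six monthly north-wall latitude series.

    Each longitude series is standardized (zero mean, unit SD over the
    fitting span); the weights are the loadings of the first principal
    component, sign-fixed so their mean is positive, rescaled to sum to 1.
    The index is the weighted average of the standardized series, so it is
    invariant to affine rescaling of any input series.
    """
    if northwall.shape[1] != 6:
        raise ValueError(f"expected 6 longitude series, got {northwall.shape[1]}")
    wall = northwall.dropna()
    if len(wall) < min_months:
        raise ValueError(f"need >= {min_months} common months, got {len(wall)}")
    sd = wall.std(ddof=1)
    if (sd <= 0).any():
        raise ValueError(
            f"constant series (zero SD): {list(sd.index[sd <= 0])}"
        )
    z = (wall - wall.mean()) / sd
    # first principal component of the standardized series
    _, _, vt = np.linalg.svd(z.to_numpy() - z.to_numpy().mean(axis=0), full_matrices=False)
    loadings = vt[0]
    if loadings.mean() < 0:
        loadings = -loadings
    weights = loadings / loadings.sum()
    index = pd.Series(z.to_numpy() @ weights, index=wall.index, name="gsnwi")
    sing = np.linalg.svd(z.to_numpy() - z.to_numpy().mean(axis=0), compute_uv=False)
    explained = float(sing[0] ** 2 / np.sum(sing ** 2))
    return GSNWISeries(
        index=index,
        weights=pd.Series(weights, index=northwall.columns, name="weight"),
        explained_var=explained,
    )
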