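"""Reduce station-level samples to bi-monthly regional mean series.

Surveys did not cover the shelf on a fixed schedule, so a bin holds the
mean over complete surveys whose midpoint falls inside it: all tows sharing
a ``cruise_id`` form one survey, the survey midpoint is halfway between its
first and last tow date, and the whole survey is assigned to the midpoint's
two-month bin.  A bin with no qualifying samples is missing, never zero.
"""

from __future__ import annotations

import logging
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .regions import RegionSpec, bin_latitude
from .structural import AbundanceSeries

logger = logging.getLogger(__name__)

__all__ = [
    "assign_bimonthly",
    "assign_region",
    "bin_latitude",
    "build_series",
    "build_temperature_series",
    "prepare_samples",
    "regional_grand_means",
]


def assign_bimonthly(d: date | str | pd.Timestamp) -> tuple[int, int]:
    """(year, bin) of a calendar date; bin = ceil(month / 2), 1..6."""
    d = pd.Timestamp(d)
    if pd.isna(d):
        raise ValueError("invalid date")
    return int(d.year), (int(d.month) + 1) // 2


def assign_region(lat: float, lon: float, regions: RegionSpec) -> str | None:
    """Region name for a position, or None when outside all regions."""
    return regions.assign(lat, lon)


def survey_midpoint(dates: pd.Series) -> pd.Timestamp:
    """Midpoint between the first and last tow date of one survey."""
    d = pd.to_datetime(dates)
    return d.min() + (d.max() - d.min()) / 2


def prepare_samples(
    samples: pd.DataFrame,
    regions: RegionSpec | None = None,
    span: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Validate samples and attach region, latitude band and survey bin.

    Rows outside all regions are dropped (counted in the log); every kept
    row carries the (year, bin) of its *survey midpoint*, so a whole cruise
    lands in one bin.
    """
    df = samples.copy()
    if df.empty:
        raise ValueError("empty sample set")
    ab = pd.to_numeric(df["abundance_ind_m3"], errors="raise")
    if not np.all(np.isfinite(ab)) or (ab < 0).any():
        raise ValueError("abundance must be finite and >= 0")
    if not df["lat_deg"].between(30, 50).all():
        raise ValueError("latitude outside [30, 50]")
    regions = regions or RegionSpec.default()
    df["region"] = [
        regions.assign(la, lo) for la, lo in zip(df["lat_deg"], df["lon_deg"])
    ]
    n_out = int(df["region"].isna().sum())
    if n_out:
        logger.info("excluded %d samples outside all regions", n_out)
    df = df[df["region"].notna()].copy()
    df["lat_band"] = [bin_latitude(la) for la in df["lat_deg"]]
    mid = df.groupby("cruise_id")["date"].transform(survey_midpoint)
    yb = [assign_bimonthly(m) for m in mid]
    df["year"] = [y for y, _ in yb]
    df["bin"] = [b for _, b in yb]
    if span is not None:
        keep = df["year"].between(*span)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("excluded %d samples outside span %s", dropped, span)
        df = df[keep].copy()
    return df


def _full_axis(span: tuple[int, int]) -> pd.DataFrame:
    return pd.DataFrame(
        [(y, b) for y in range(span[0], span[1] + 1) for b in range(1, 7)],
        columns=["year", "bin"],
    )


def build_series(
    samples: pd.DataFrame,
    species: str,
    region: str,
    span: tuple[int, int],
    regions: RegionSpec | None = None,
    prepared: bool = False,
) -> AbundanceSeries:
    """Bi-monthly mean-abundance series for one species x region.

    The value of a bin is the arithmetic mean over all qualifying tows;
    bins without samples are NaN.  The returned series covers ``span``
    contiguously (6 bins per year).
    """
    df = samples if prepared else prepare_samples(samples, regions, span)
    sub = df[(df["species"] == species) & (df["region"] == region)]
    g = sub.groupby(["year", "bin"])["abundance_ind_m3"].agg(["mean", "size"])
    axis = _full_axis(span)
    merged = axis.merge(
        g.rename(columns={"mean": "value", "size": "n_samples"}),
        on=["year", "bin"],
        how="left",
    )
    merged["n_samples"] = merged["n_samples"].fillna(0).astype(int)
    return AbundanceSeries(species=species, region=region, data=merged)


def build_temperature_series(
    samples: pd.DataFrame,
    region: str,
    span: tuple[int, int],
    regions: RegionSpec | None = None,
    prepared: bool = False,
) -> AbundanceSeries:
    """Bi-monthly mean upper-3-m temperature for one region.

    Station temperature is recorded once per tow regardless of species, so
    duplicate (station, temperature) rows across species are collapsed
    before averaging.  Bins where every temperature is missing are NaN.
    """
    df = samples if prepared else prepare_samples(samples, regions, span)
    sub = df[df["region"] == region]
    sta = sub.drop_duplicates("station_id")
    sta = sta[pd.to_numeric(sta["temp_c"], errors="coerce").notna()]
    g = sta.groupby(["year", "bin"])["temp_c"].agg(["mean", "size"])
    axis = _full_axis(span)
    merged = axis.merge(
        g.rename(columns={"mean": "value", "size": "n_samples"}),
        on=["year", "bin"],
        how="left",
    )
    merged["n_samples"] = merged["n_samples"].fillna(0).astype(int)
    return AbundanceSeries(species="TEMP", region=region, data=merged)


def regional_grand_means(
    samples: pd.DataFrame,
    regions: RegionSpec | None = None,
    span: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Mean and SD of abundance over all tows, per species x region.

    This is the summary the survey reports as regional grand means
    (e.g. "233 +/- 213 ind m^-3"); on synthetic input it describes the
    synthetic world, not the real shelf.
    """
    df = prepare_samples(samples, regions, span)
    out = (
        df.groupby(["species", "region"])["abundance_ind_m3"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
    )
    return out


def series_to_frame(series_list: list[AbundanceSeries]) -> pd.DataFrame:
    """Tidy CSV layout: species, region, year, bin, mean_abundance, n_samples."""
    frames = []
    for s in series_list:
        d = s.data.copy()
        d.insert(0, "region", s.region)
        d.insert(0, "species", s.species)
        frames.append(d.rename(columns={"value": "mean_abundance"}))
    return pd.concat(frames, ignore_index=True)
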