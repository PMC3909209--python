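"""Synthetic survey, altimetry and Gulf Stream data with known ground truth.

Generates the three inputs the pipeline consumes, at desk scale and with
every stochastic ingredient controlled by one seed:

* station-level plankton samples (bi-monthly cruises per sub-region,
  1977-2009 by default, with the southern 1989-1991 sampling gap),
* weekly gridded velocity fields on a 1/3-degree grid spanning 35-45N with
  a mean southward alongshore flow,
* a monthly Gulf Stream north-wall latitude series at six longitudes
  sharing one common signal, which is (negatively, by default) coupled into
  the alongshore velocity.

Per-sample abundance is max(0, trend + seasonal + AR(1) bin noise +
station noise); the station noise is mean-zero shifted-lognormal
(right-skewed, like tow counts) with standard deviation ``sigma_eps``, so
the zero-noise configuration reproduces the deterministic signal exactly.
Ground truth (trend paths, seasonal coefficients, the common north-wall
signal) is retained on the truth object for recovery tests.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from datetime import date, timedelta

import numpy as np
import pandas as pd
import xarray as xr

from .regions import RegionSpec
from .structural import harmonic_design

logger = logging.getLogger(__name__)

SPECIES = ("CFIN", "CTYP")

# fixed RNG stream ids so each output is reproducible independently
_STREAM_AR = 1
_STREAM_STATION = 2
_STREAM_POS = 3
_STREAM_TEMP = 4
_STREAM_SIGNAL = 7
_STREAM_VEL_ANOM = 8
_STREAM_VEL_NOISE = 9
_STREAM_WALL = 10

NORTHWALL_LONGITUDES = (79, 75, 72, 70, 67, 65)  # degrees West
_WALL_BASE_LAT = (35.2, 36.5, 38.2, 39.5, 40.3, 40.9)

_LOGNORM_SHAPE = 0.6  # skewness of the station noise, fixed


def seasonal_from_peak(amplitude: float, peak_bin: int) -> tuple:
    """First-harmonic coefficients (a1, b1, 0, 0, 0) peaking at ``peak_bin``."""
    t_peak = peak_bin - 1
    w = 2.0 * math.pi / 6.0
    return (
        amplitude * math.cos(w * t_peak),
        amplitude * math.sin(w * t_peak),
        0.0,
        0.0,
        0.0,
    )


@dataclass(frozen=True)
class RegionTruth:
    """Deterministic abundance signal for one species in one region."""

    level: float                 # long-term mean, ind m^-3
    drift: float = 0.0           # ind m^-3 per year
    cycle_amp: float = 0.0       # multi-year cycle amplitude, ind m^-3
    cycle_period: float = 11.0   # years
    seasonal: tuple = (0.0, 0.0, 0.0, 0.0, 0.0)
    seasonal_late: tuple | None = None   # coefficients after shift_year
    shift_year: int | None = None

    def seasonal_at(self, year: int) -> np.ndarray:
        if self.shift_year is not None and year >= self.shift_year:
            return np.asarray(self.seasonal_late, dtype=float)
        return np.asarray(self.seasonal, dtype=float)

    def trend_at(self, year_frac: np.ndarray | float, mid_year: float) -> np.ndarray:
        yf = np.asarray(year_frac, dtype=float)
        return (
            self.level
            + self.drift * (yf - mid_year)
            + self.cycle_amp * np.sin(2.0 * math.pi * (yf - mid_year) / self.cycle_period)
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """All parameters of the synthetic world, with the seed."""

    seed: int = 0
    years: tuple = (1977, 2009)
    species: dict = field(default_factory=dict)  # species -> region -> RegionTruth
    phi_true: float = 0.95
    sigma_eta: float = 5.0
    sigma_eps: float = 30.0
    gap_spec: tuple = ()                 # ((region, (y0, y1)), ...)
    stations_per_bin: int = 6
    temp_mean: dict = field(default_factory=dict)
    temp_amp: float = 8.0
    temp_noise_sd: float = 0.4
    # biology <- physics coupling: (ind m^-3) per (cm/s) of the yearly
    # velocity anomaly, per species; empty = biology independent of physics
    coupling_velocity_abundance: dict = field(default_factory=dict)
    # physics
    velocity_years: tuple = (1993, 2010)
    mean_alongshore: float = -5.0        # cm/s, negative = southward
    coupling_gsnwi_velocity: float = -1.5
    velocity_noise_sd: float = 2.0
    annual_anomaly_sd: float = 1.5
    lon_range: tuple = (-76.0, -69.0)
    coast_lon: float = -74.0
    # north wall
    wall_yearly_sd: float = 1.0
    wall_monthly_sd: float = 0.3
    wall_signal_scale: float = 0.5       # degrees latitude per unit signal
    wall_noise_sd: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.phi_true <= 1.0):
            raise ValueError("phi_true must lie in (0, 1]")
        for name in ("sigma_eta", "sigma_eps", "temp_noise_sd",
                     "velocity_noise_sd", "annual_anomaly_sd",
                     "wall_yearly_sd", "wall_monthly_sd", "wall_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.stations_per_bin < 0:
            raise ValueError("stations_per_bin must be >= 0")
        if self.years[1] < self.years[0]:
            raise ValueError("empty year span")
        lo, hi = self.velocity_years
        if lo < 1992 or hi > 2011:
            logger.warning(
                "velocity span %s outside the 1992-2011 altimetry analogue", self.velocity_years
            )

    @property
    def mid_year(self) -> float:
        return 0.5 * (self.years[0] + self.years[1])

    def region_names(self) -> list[str]:
        names: list[str] = []
        for per_region in self.species.values():
            for r in per_region:
                if r not in names:
                    names.append(r)
        return names

    def in_gap(self, region: str, year: int) -> bool:
        return any(r == region and y0 <= year <= y1 for r, (y0, y1) in self.gap_spec)

    # ---- serialization -------------------------------------------------
    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["species"] = {
            sp: {
                r: RegionTruth(
                    **{
                        **rt,
                        "seasonal": tuple(rt["seasonal"]),
                        "seasonal_late": tuple(rt["seasonal_late"])
                        if rt.get("seasonal_late") is not None
                        else None,
                    }
                )
                for r, rt in per.items()
            }
            for sp, per in d["species"].items()
        }
        for key in ("years", "velocity_years", "lon_range"):
            d[key] = tuple(d[key])
        d["gap_spec"] = tuple((r, tuple(rng)) for r, rng in d["gap_spec"])
        return cls(**d)


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The study-condition defaults.

    Regional mean levels follow the printed order of magnitude for the two
    species (C. finmarchicus largest in the GOM, Cen. typicus largest in
    the MAB); seasonal peaks sit in May-June for C. finmarchicus
    everywhere, while the MAB Cen. typicus peak shifts from Nov-Dec to
    Jan-Feb after 1985.  The southern regions carry the 1989-1991 sampling
    gap.  Trend/noise parameters (phi=0.95, sigma_eta=5, sigma_eps=30) are
    the reference conditions of the recovery experiments.
    """
    cfin = {
        "GOM": RegionTruth(233.0, cycle_amp=25.0, seasonal=seasonal_from_peak(180.0, 3)),
        "GB": RegionTruth(183.0, cycle_amp=15.0, seasonal=seasonal_from_peak(150.0, 3)),
        "SNE": RegionTruth(152.0, cycle_amp=30.0, seasonal=seasonal_from_peak(120.0, 3)),
        "MAB": RegionTruth(55.0, cycle_amp=20.0, seasonal=seasonal_from_peak(45.0, 3)),
    }
    ctyp = {
        "GOM": RegionTruth(169.0, cycle_amp=20.0, seasonal=seasonal_from_peak(130.0, 6)),
        "GB": RegionTruth(211.0, cycle_amp=40.0, seasonal=seasonal_from_peak(160.0, 6)),
        "SNE": RegionTruth(342.0, cycle_amp=40.0, seasonal=seasonal_from_peak(250.0, 6)),
        "MAB": RegionTruth(
            493.0,
            cycle_amp=50.0,
            seasonal=seasonal_from_peak(350.0, 6),
            seasonal_late=seasonal_from_peak(350.0, 1),
            shift_year=1985,
        ),
    }
    temp_mean = {"GOM": 8.0, "GB": 9.5, "SNE": 11.5, "MAB": 13.5}
    base = dict(
        seed=seed,
        species={"CFIN": cfin, "CTYP": ctyp},
        gap_spec=(("SNE", (1989, 1991)), ("MAB", (1989, 1991))),
        temp_mean=temp_mean,
    )
    base.update(overrides)
    return SyntheticTruth(**base)


# --------------------------------------------------------------------------
# deterministic signal helpers (ground truth for tests)
# --------------------------------------------------------------------------

def _bin_axis(years: tuple) -> pd.DataFrame:
    y0, y1 = years
    idx = [(y, b) for y in range(y0, y1 + 1) for b in range(1, 7)]
    df = pd.DataFrame(idx, columns=["year", "bin"])
    df["t_abs"] = df["year"] * 6 + df["bin"] - 1
    df["year_frac"] = df["year"] + (df["bin"] - 0.5) / 6.0
    return df


def bin_truth(truth: SyntheticTruth, species: str, region: str) -> pd.DataFrame:
    """Deterministic bin-mean signal trend_t + seasonal_t (no noise)."""
    rt = truth.species[species][region]
    ax = _bin_axis(truth.years)
    trend = rt.trend_at(ax["year_frac"].to_numpy(), truth.mid_year)
    X = harmonic_design(ax["t_abs"].to_numpy())
    seasonal = np.array(
        [X[i] @ rt.seasonal_at(int(y)) for i, y in enumerate(ax["year"])]
    )
    out = ax[["year", "bin"]].copy()
    out["trend"] = trend
    out["seasonal"] = seasonal
    out["signal"] = trend + seasonal
    return out


def _ar1_path(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    if sigma == 0:
        return np.zeros(n)
    x = np.empty(n)
    prev = rng.normal(scale=sigma / math.sqrt(1 - phi * phi)) if phi < 1 else 0.0
    eta = rng.normal(scale=sigma, size=n)
    for i in range(n):
        prev = phi * prev + eta[i]
        x[i] = prev
    return x


def _station_noise(size, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Mean-zero, right-skewed additive noise with SD ``sigma``."""
    if sigma == 0:
        return np.zeros(size) if size is not None else 0.0
    s = _LOGNORM_SHAPE
    z = rng.normal(size=size)
    l = np.exp(s * z - 0.5 * s * s) - 1.0      # mean 0, var exp(s^2)-1
    return sigma * l / math.sqrt(math.expm1(s * s))


def temp_at(truth: SyntheticTruth, region: str, when: date) -> float:
    """Deterministic upper-3-m temperature at a date (no noise)."""
    doy = when.timetuple().tm_yday
    mean = truth.temp_mean.get(region, 10.0)
    return mean - truth.temp_amp * math.cos(2.0 * math.pi * (doy - 233) / 365.25)


# --------------------------------------------------------------------------
# abundance samples
# --------------------------------------------------------------------------

def generate_abundance(
    truth: SyntheticTruth,
    regions: RegionSpec | None = None,
) -> pd.DataFrame:
    """Station-level sample table for all species and regions.

    One cruise per (region, bi-monthly bin) outside the configured gaps,
    ``stations_per_bin`` stations per cruise, one row per station and
    species.  Columns: cruise_id, station_id, date, lat_deg, lon_deg,
    species, abundance_ind_m3, temp_c.
    """
    regions = regions or RegionSpec.default()
    region_names = truth.region_names() or list(regions.names)
    ax = _bin_axis(truth.years)
    nbins = len(ax)

    # per-(species, region) AR(1) bin noise
    ar = {
        (sp, r): _ar1_path(
            nbins, truth.phi_true, truth.sigma_eta,
            np.random.default_rng([truth.seed, _STREAM_AR, si, ri]),
        )
        for si, sp in enumerate(SPECIES) if sp in truth.species
        for ri, r in enumerate(region_names)
    }
    pos_rng = np.random.default_rng([truth.seed, _STREAM_POS])
    sta_rng = np.random.default_rng([truth.seed, _STREAM_STATION])
    tmp_rng = np.random.default_rng([truth.seed, _STREAM_TEMP])

    signals = {
        (sp, r): bin_truth(truth, sp, r)["signal"].to_numpy()
        for sp in truth.species
        for r in truth.species[sp]
    }
    if truth.coupling_velocity_abundance:
        anom = velocity_annual_anomaly(truth)
        bump = np.array(
            [anom.get(int(y), 0.0) for y in ax["year"]]
        )
        for (sp, r) in signals:
            coef = truth.coupling_velocity_abundance.get(sp, 0.0)
            if coef:
                signals[(sp, r)] = signals[(sp, r)] + coef * bump

    rows = []
    for ri, region in enumerate(region_names):
        lon0, lat0, lon1, lat1 = regions.bounds(region)
        pad_lat = 0.05 * (lat1 - lat0)
        pad_lon = 0.05 * (lon1 - lon0)
        for i in range(nbins):
            year, b = int(ax.loc[i, "year"]), int(ax.loc[i, "bin"])
            if truth.in_gap(region, year):
                continue
            m0 = 2 * b - 1
            start = date(year, m0, 4)
            end = date(year, m0 + 1, 24)
            cruise = f"C{year}{b}{region}"
            ns = truth.stations_per_bin
            lats = pos_rng.uniform(lat0 + pad_lat, lat1 - pad_lat, ns)
            lons = pos_rng.uniform(lon0 + pad_lon, lon1 - pad_lon, ns)
            offsets = np.linspace(0, (end - start).days, ns) if ns > 1 else [
                (end - start).days // 2
            ]
            for k in range(ns):
                d = start + timedelta(days=int(round(offsets[k])))
                temp = temp_at(truth, region, d) + (
                    tmp_rng.normal(scale=truth.temp_noise_sd)
                    if truth.temp_noise_sd > 0 else 0.0
                )
                for sp in truth.species:
                    if region not in truth.species[sp]:
                        continue
                    m = signals[(sp, region)][i] + ar[(sp, region)][i]
                    ab = max(
                        0.0,
                        m + _station_noise(None, truth.sigma_eps, sta_rng),
                    )
                    rows.append(
                        (
                            cruise,
                            f"{cruise}_S{k + 1}",
                            d.isoformat(),
                            round(float(lats[k]), 4),
                            round(float(lons[k]), 4),
                            sp,
                            float(ab),
                            round(float(temp), 3),
                        )
                    )
    df = pd.DataFrame(
        rows,
        columns=[
            "cruise_id", "station_id", "date", "lat_deg", "lon_deg",
            "species", "abundance_ind_m3", "temp_c",
        ],
    )
    logger.info("generated %d sample rows", len(df))
    return df


# --------------------------------------------------------------------------
# common signal, north wall and velocity grid
# --------------------------------------------------------------------------

def _month_axis(years: tuple) -> pd.DatetimeIndex:
    y0, y1 = years
    return pd.date_range(f"{y0}-01-01", f"{y1}-12-01", freq="MS")


def velocity_annual_anomaly(truth: SyntheticTruth) -> dict[int, float]:
    """The i.i.d. yearly anomaly of the alongshore flow (cm/s), by year.

    Drawn from its own stream so the abundance generator can couple onto
    the same anomalies the velocity grid carries.
    """
    rng = np.random.default_rng([truth.seed, _STREAM_VEL_ANOM])
    years = list(range(truth.velocity_years[0], truth.velocity_years[1] + 1))
    return dict(zip(years, rng.normal(scale=truth.annual_anomaly_sd, size=len(years))))


def gsnwi_common_signal(truth: SyntheticTruth) -> pd.Series:
    """Monthly common signal shared by the north wall and the velocity field.

    A yearly i.i.d. level plus white monthly noise, so annual aggregates of
    independent replicates are exchangeable (the null-calibration regime).
    """
    months = _month_axis(truth.velocity_years)
    rng = np.random.default_rng([truth.seed, _STREAM_SIGNAL])
    years = sorted(set(months.year))
    yearly = dict(zip(years, rng.normal(scale=truth.wall_yearly_sd, size=len(years))))
    monthly = (
        rng.normal(scale=truth.wall_monthly_sd, size=len(months))
        if truth.wall_monthly_sd > 0 else np.zeros(len(months))
    )
    vals = np.array([yearly[m.year] for m in months]) + monthly
    return pd.Series(vals, index=months, name="signal")


def generate_northwall(truth: SyntheticTruth) -> pd.DataFrame:
    """Monthly north-wall latitudes at the six reference longitudes.

    Columns are labeled "79W" ... "65W"; each series is a fixed base
    latitude plus ``wall_signal_scale`` times the common signal plus
    independent noise.
    """
    sig = gsnwi_common_signal(truth)
    rng = np.random.default_rng([truth.seed, _STREAM_WALL])
    data = {}
    for base, lonw in zip(_WALL_BASE_LAT, NORTHWALL_LONGITUDES):
        noise = (
            rng.normal(scale=truth.wall_noise_sd, size=len(sig))
            if truth.wall_noise_sd > 0 else np.zeros(len(sig))
        )
        data[f"{lonw}W"] = base + truth.wall_signal_scale * sig.to_numpy() + noise
    df = pd.DataFrame(data, index=sig.index)
    df.index.name = "month"
    return df


def generate_velocity_grid(truth: SyntheticTruth) -> xr.Dataset:
    """Weekly geostrophic velocity fields on a 1/3-degree grid, 35-45N.

    v (northward, cm/s) = mean_alongshore + yearly anomaly +
    coupling * common signal + white noise; u is white noise.  Cells west
    of ``coast_lon`` are land (NaN).
    """
    lats = np.round(np.arange(35.0, 45.0 + 1e-9, 1.0 / 3.0), 4)
    lon0, lon1 = truth.lon_range
    lons = np.round(np.arange(lon0, lon1 + 1e-9, 1.0 / 3.0), 4)
    y0, y1 = truth.velocity_years
    times = pd.date_range(f"{y0}-01-04", f"{y1}-12-28", freq="7D")

    sig = gsnwi_common_signal(truth)
    sig_w = sig.reindex(times.to_period("M").to_timestamp(), method=None)
    sig_w = pd.Series(sig_w.to_numpy(), index=times).to_numpy()

    yearly = velocity_annual_anomaly(truth)
    anom_w = np.array([yearly[t.year] for t in times])

    noise_rng = np.random.default_rng([truth.seed, _STREAM_VEL_NOISE])
    shape = (len(times), len(lats), len(lons))
    vnoise = (
        noise_rng.normal(scale=truth.velocity_noise_sd, size=shape)
        if truth.velocity_noise_sd > 0 else np.zeros(shape)
    )
    unoise = (
        noise_rng.normal(scale=truth.velocity_noise_sd, size=shape)
        if truth.velocity_noise_sd > 0 else np.zeros(shape)
    )

    base = (
        truth.mean_alongshore
        + anom_w[:, None, None]
        + truth.coupling_gsnwi_velocity * sig_w[:, None, None]
    )
    v = base + vnoise
    u = unoise
    land = lons[None, :] < truth.coast_lon  # broadcast over lat rows
    land3 = np.broadcast_to(land, (len(lats), len(lons)))
    v[:, land3] = np.nan
    u[:, land3] = np.nan

    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), u, {"units": "cm s-1"}),
            "v": (("time", "lat", "lon"), v, {"units": "cm s-1", "positive": "northward"}),
        },
        coords={"time": times, "lat": lats, "lon": lons},
        attrs={"grid_spacing_deg": 1.0 / 3.0, "coast_lon": truth.coast_lon},
    )
    return ds


# --------------------------------------------------------------------------
# writers
# --------------------------------------------------------------------------

def write_outputs(truth: SyntheticTruth, outdir, regions: RegionSpec | None = None):
    """Write samples, velocity grid (long CSV), north wall and truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    samples = generate_abundance(truth, regions)
    samples.to_csv(outdir / "samples.csv", index=False)
    wall = generate_northwall(truth)
    wall.to_csv(outdir / "northwall.csv")
    grid = generate_velocity_grid(truth)
    long = grid.to_dataframe().reset_index()
    long.to_csv(outdir / "velocity.csv", index=False)
    (outdir / "truth.json").write_text(truth.to_json())
    return {
        "samples": outdir / "samples.csv",
        "northwall": outdir / "northwall.csv",
        "velocity": outdir / "velocity.csv",
        "truth": outdir / "truth.json",
    }
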