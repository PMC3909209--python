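"""Binning rules: bi-monthly assignment, regions, latitude bands, means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from shapely.geometry import box

from copetrend import ingest, synthetic
from copetrend.regions import RegionSpec, bin_latitude


@pytest.mark.parametrize(
    "date,expected",
    [
        ("1985-01-15", (1985, 1)),
        ("1985-12-31", (1985, 6)),
        ("2000-06-30", (2000, 3)),
        ("2000-07-01", (2000, 4)),
    ],
)
def test_assign_bimonthly(date, expected):
    assert ingest.assign_bimonthly(date) == expected


def test_assign_bimonthly_rejects_invalid():
    with pytest.raises(ValueError):
        ingest.assign_bimonthly("not-a-date")


def test_survey_midpoint_assigns_whole_cruise():
    """A cruise spanning Feb 20 - Mar 10 has midpoint Mar 1, so every tow
    lands in bin 2 even though some tows were taken in February."""
    rows = []
    for i, d in enumerate(["1985-02-20", "1985-02-25", "1985-03-10"]):
        rows.append(("CR1", f"CR1_S{i}", d, 43.0, -68.0, "CFIN", 10.0 * (i + 1), 5.0))
    df = pd.DataFrame(rows, columns=[
        "cruise_id", "station_id", "date", "lat_deg", "lon_deg",
        "species", "abundance_ind_m3", "temp_c"])
    assert ingest.survey_midpoint(df["date"]) == pd.Timestamp("1985-03-01")
    prep = ingest.prepare_samples(df)
    assert (prep["bin"] == 2).all() and (prep["year"] == 1985).all()


class TestRegions:
    def test_containment_and_exclusion(self):
        regions = RegionSpec.default()
        assert regions.assign(43.0, -68.0) == "GOM"
        assert regions.assign(37.0, -74.0) == "MAB"
        assert regions.assign(34.0, -74.0) is None  # south of all regions

    def test_boundary_tie_break_goes_to_first_in_config(self):
        # GOM/GB share the 42N edge east of 69W; GOM is listed first
        regions = RegionSpec.default()
        assert regions.assign(42.0, -68.0) == "GOM"

    def test_overlapping_regions_rejected_at_validation(self):
        with pytest.raises(ValueError, match="overlap"):
            RegionSpec(["A", "B"], [box(-70, 40, -68, 42), box(-69, 41, -67, 43)])

    def test_yaml_roundtrip(self, tmp_path):
        regions = RegionSpec.default()
        p = tmp_path / "regions.yaml"
        import yaml

        p.write_text(yaml.safe_dump(regions.to_dict()))
        again = RegionSpec.from_yaml(p)
        assert again.names == regions.names
        assert again.assign(43.0, -68.0) == "GOM"


@pytest.mark.parametrize(
    "lat,band",
    [(35.5, "35-37"), (37.0, "37-39"), (43.2, "43-45"), (36.999, "35-37"),
     (34.9, None), (45.0, None)],
)
def test_bin_latitude_half_open(lat, band):
    assert bin_latitude(lat) == band


class TestBuildSeries:
    def test_full_coverage_length_198(self):
        truth = synthetic.default_truth(seed=1, years=(1977, 2009), gap_spec=(),
                                        stations_per_bin=1)
        samples = synthetic.generate_abundance(truth)
        s = ingest.build_series(samples, "CFIN", "GOM", truth.years)
        assert len(s.data) == 198
        assert s.n_obs == 198

    def test_bin_mean_is_arithmetic_mean(self):
        df = _toy_samples([10.0, 20.0, 30.0])
        s = ingest.build_series(df, "CFIN", "GOM", (1985, 1985))
        assert s.data.loc[0, "value"] == pytest.approx(20.0)
        assert s.data.loc[0, "n_samples"] == 3

    def test_gap_gives_18_consecutive_missing_bins(self, ):
        truth = synthetic.default_truth(
            seed=2, years=(1987, 1993), stations_per_bin=1,
            gap_spec=(("MAB", (1989, 1991)),))
        samples = synthetic.generate_abundance(truth)
        s = ingest.build_series(samples, "CTYP", "MAB", truth.years)
        miss = np.flatnonzero(~np.isfinite(s.values))
        assert len(miss) == 18
        assert np.all(np.diff(miss) == 1)

    def test_missing_is_not_zero(self):
        df = _toy_samples([10.0, 20.0])
        s = ingest.build_series(df, "CFIN", "GOM", (1985, 1985))
        with_zero = pd.concat(
            [df, _toy_samples([0.0], station_offset=10)], ignore_index=True
        )
        s0 = ingest.build_series(with_zero, "CFIN", "GOM", (1985, 1985))
        assert s0.data.loc[0, "value"] == pytest.approx(10.0)  # zero changes the mean
        other = ingest.build_series(df, "CTYP", "GOM", (1985, 1985))
        assert np.isnan(other.data.loc[0, "value"])  # no samples -> missing

    def test_permutation_invariance(self, small_samples, small_truth):
        s1 = ingest.build_series(small_samples, "CFIN", "GB", small_truth.years)
        shuffled = small_samples.sample(frac=1.0, random_state=3).reset_index(drop=True)
        s2 = ingest.build_series(shuffled, "CFIN", "GB", small_truth.years)
        pd.testing.assert_frame_equal(s1.data, s2.data)

    def test_sample_conservation(self, small_samples, small_truth):
        prep = ingest.prepare_samples(small_samples, span=small_truth.years)
        for (sp, reg), grp in prep.groupby(["species", "region"]):
            s = ingest.build_series(prep, sp, reg, small_truth.years, prepared=True)
            assert s.data["n_samples"].sum() == len(grp)

    def test_empty_sample_set_rejected(self):
        with pytest.raises(ValueError):
            ingest.build_series(_toy_samples([]).iloc[:0], "CFIN", "GOM", (1985, 1985))


class TestTemperature:
    def test_bin_mean_and_all_missing(self):
        df = _toy_samples([10.0, 20.0], temps=[5.0, 7.0])
        s = ingest.build_temperature_series(df, "GOM", (1985, 1985))
        assert s.data.loc[0, "value"] == pytest.approx(6.0)
        df2 = _toy_samples([10.0], temps=[np.nan])
        s2 = ingest.build_temperature_series(df2, "GOM", (1985, 1985))
        assert np.isnan(s2.data.loc[0, "value"])

    def test_recovers_generator_cycle(self):
        truth = synthetic.default_truth(
            seed=3, years=(1990, 1991), temp_noise_sd=0.0, stations_per_bin=2,
            gap_spec=())
        samples = synthetic.generate_abundance(truth)
        s = ingest.build_temperature_series(samples, "GOM", truth.years)
        prep = ingest.prepare_samples(samples, span=truth.years)
        gom = prep[prep.region == "GOM"].drop_duplicates("station_id")
        expected = [
            synthetic.temp_at(truth, "GOM", pd.Timestamp(d).date())
            for d in gom[(gom["bin"] == 4) & (gom["year"] == 1990)]["date"]
        ]
        # sample temperatures are written rounded to 3 decimals
        assert s.data.set_index(["year", "bin"]).loc[(1990, 4), "value"] == pytest.approx(
            np.mean(expected), abs=2e-3
        )


def test_grand_means_on_hand_computable_fixture():
    df = pd.concat(
        [_toy_samples([10.0, 20.0, 30.0]),
         _toy_samples([100.0, 200.0], region="MAB", species="CTYP")],
        ignore_index=True,
    )
    gm = ingest.regional_grand_means(df).set_index(["species", "region"])
    assert gm.loc[("CFIN", "GOM"), "mean"] == pytest.approx(20.0)
    assert gm.loc[("CFIN", "GOM"), "sd"] == pytest.approx(10.0)
    assert gm.loc[("CTYP", "MAB"), "mean"] == pytest.approx(150.0)


def _toy_samples(abunds, region="GOM", species="CFIN", temps=None, station_offset=0):
    lat, lon = (43.0, -68.0) if region == "GOM" else (37.0, -74.0)
    temps = temps if temps is not None else [5.0] * len(abunds)
    rows = [
        (f"CR_{region}", f"CR_{region}_S{station_offset + i}", "1985-01-15",
         lat, lon, species, a, t)
        for i, (a, t) in enumerate(zip(abunds, temps))
    ]
    return pd.DataFrame(rows, columns=[
        "cruise_id", "station_id", "date", "lat_deg", "lon_deg",
        "species", "abundance_ind_m3", "temp_c"])
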