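"""Transport path rule, aggregations, and the PCA-weighted GSNWI."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from hypothesis import given, strategies as st

from copetrend import forcing, synthetic


def _toy_grid(path_values, n_land=1, n_times=4, lat=39.33):
    """One-row grid: ``n_land`` NaN cells at the coast then the path cells."""
    lons = -74.0 - n_land / 3.0 + np.arange(n_land + len(path_values)) / 3.0
    times = pd.date_range("2000-01-05", periods=n_times, freq="7D")
    v = np.tile(
        np.concatenate([[np.nan] * n_land, np.asarray(path_values, float)]),
        (n_times, 1, 1),
    )
    return xr.Dataset(
        {"v": (("time", "lat", "lon"), v), "u": (("time", "lat", "lon"), v * 0)},
        coords={"time": times, "lat": [lat], "lon": lons},
        attrs={"grid_spacing_deg": 1 / 3},
    )


class TestPathVelocity:
    def test_printed_toy_field(self):
        """Coast-to-sea cells [9, 9, -4, -6, -2, -8]: drop the two nearest
        the coast, mean of the remaining four is -5 cm/s."""
        grid = _toy_grid([9.0, 9.0, -4.0, -6.0, -2.0, -8.0])
        vel = forcing.path_velocity(grid)
        assert np.allclose(vel, -5.0)
        assert vel.attrs["n_cells_averaged"] == 4

    def test_uniform_field(self):
        grid = _toy_grid([-5.0] * 6)
        assert np.allclose(forcing.path_velocity(grid), -5.0)

    def test_linearity_in_the_field(self):
        grid = _toy_grid([9.0, 9.0, -4.0, -6.0, -2.0, -8.0])
        doubled = grid.copy()
        doubled["v"] = grid["v"] * 2
        np.testing.assert_allclose(
            forcing.path_velocity(doubled), 2 * forcing.path_velocity(grid)
        )

    def test_too_few_path_cells_is_an_error(self):
        grid = _toy_grid([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="cells"):
            forcing.path_velocity(grid)

    def test_missing_cell_on_path_listed(self):
        vals = [9.0, 9.0, -4.0, np.nan, -2.0, -8.0]
        grid = _toy_grid(vals)
        with pytest.raises(ValueError, match="-73"):
            forcing.path_velocity(grid)


class TestAggregation:
    def test_bimonthly_mean_and_boundary_convention(self):
        times = pd.date_range("2000-01-05", "2000-02-28", freq="7D")
        s = pd.Series(-3.0, index=times)
        bim = forcing.to_bimonthly(s)
        assert bim.loc[(2000, 1)] == pytest.approx(-3.0)
        # a week stamped March 1 belongs to bin 2 even if it covers February
        s2 = pd.Series([1.0], index=pd.DatetimeIndex(["2000-03-01"]))
        assert forcing.to_bimonthly(s2).loc[(2000, 2)] == pytest.approx(1.0)

    def test_empty_bins_are_missing(self):
        s = pd.Series([1.0], index=pd.DatetimeIndex(["2000-01-05"]))
        bim = forcing.to_bimonthly(s)
        assert np.isnan(bim.loc[(2000, 3)])

    def test_annual_components_signs_and_one_sided_year(self):
        idx = pd.MultiIndex.from_product([[2000], range(1, 7)], names=["year", "bin"])
        s = pd.Series([2.0, -3.0, 0.0, -1.0, 0.5, -0.5], index=idx)
        out = forcing.annual_cumulative(s).set_index("year")
        assert out.loc[2000, "north_sum"] == pytest.approx(2.5)
        assert out.loc[2000, "south_sum"] == pytest.approx(-4.5)
        allsouth = forcing.annual_cumulative(pd.Series(-1.0, index=idx))
        assert allsouth.loc[0, "north_sum"] == 0.0

    @given(st.lists(st.floats(-10, 10), min_size=6, max_size=6))
    def test_north_plus_south_equals_plain_sum(self, vals):
        idx = pd.MultiIndex.from_product([[2001], range(1, 7)], names=["year", "bin"])
        s = pd.Series(vals, index=idx)
        out = forcing.annual_cumulative(s).iloc[0]
        assert out["north_sum"] + out["south_sum"] == pytest.approx(sum(vals))
        assert out["north_sum"] >= 0 >= out["south_sum"]


class TestGSNWI:
    def _wall(self, seed=0, noise=0.3, months=60):
        rng = np.random.default_rng(seed)
        sig = rng.normal(size=months)
        idx = pd.date_range("1995-01-01", periods=months, freq="MS")
        data = {
            f"{lon}W": 38.0 + 0.5 * sig + noise * rng.normal(size=months)
            for lon in (79, 75, 72, 70, 67, 65)
        }
        return pd.DataFrame(data, index=idx), pd.Series(sig, index=idx)

    def test_identical_series_give_equal_weights(self):
        wall, sig = self._wall(noise=0.0)
        gs = forcing.gsnwi(wall)
        np.testing.assert_allclose(gs.weights, 1 / 6, atol=1e-12)
        z = (sig - sig.mean()) / sig.std(ddof=1)
        np.testing.assert_allclose(gs.index, z, atol=1e-9)

    def test_index_beats_any_single_longitude(self):
        wall, sig = self._wall(seed=3, noise=0.6)
        gs = forcing.gsnwi(wall)
        r_index = np.corrcoef(gs.index, sig)[0, 1]
        r_single = [np.corrcoef(wall[c], sig)[0, 1] for c in wall.columns]
        assert r_index > max(r_single)

    def test_inputs_correlate_positively_with_index(self):
        wall, _ = self._wall(seed=5, noise=0.8)
        gs = forcing.gsnwi(wall)
        for c in wall.columns:
            assert np.corrcoef(wall[c], gs.index)[0, 1] > 0

    def test_affine_rescaling_invariance(self):
        wall, _ = self._wall(seed=7)
        gs1 = forcing.gsnwi(wall)
        wall2 = wall.copy()
        wall2["72W"] = wall2["72W"] * 3.2 + 11.0
        gs2 = forcing.gsnwi(wall2)
        np.testing.assert_allclose(gs1.index, gs2.index, atol=1e-9)
        np.testing.assert_allclose(gs1.weights, gs2.weights, atol=1e-9)

    def test_degenerate_inputs_rejected(self):
        wall, _ = self._wall()
        with pytest.raises(ValueError, match="6 longitude"):
            forcing.gsnwi(wall.iloc[:, :5])
        wall_const = wall.copy()
        wall_const["70W"] = 38.0
        with pytest.raises(ValueError, match="zero SD"):
            forcing.gsnwi(wall_const)
        with pytest.raises(ValueError, match="24"):
            forcing.gsnwi(wall.iloc[:10])
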