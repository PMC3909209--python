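"""Structural model: state space, likelihood vs dense oracle, fitting."""

import numpy as np
import pandas as pd
import pytest

from copetrend.structural import (
    AbundanceSeries,
    ModelSpec,
    StructuralParams,
    build_state_space,
    dense_loglik,
    dense_smoothed_trend,
    fit,
    harmonic_design,
    kalman_loglik,
    simulate_structural,
    split_periods,
)
from conftest import make_series


def _random_instance(seed, n=20, n_missing=3, phi=None):
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.15, 0.98) if phi is None else phi
    params = StructuralParams(
        phi=phi,
        sigma2_eta=rng.uniform(0.3, 5.0),
        sigma2_eps=rng.uniform(0.3, 5.0),
        seasonal=rng.normal(scale=3.0, size=5),
    )
    y = simulate_structural(n, params, rng)
    if n_missing:
        y[rng.choice(n, n_missing, replace=False)] = np.nan
    return y, params


class TestStateSpace:
    def test_state_dimension_is_six(self):
        ss = build_state_space(ModelSpec())
        assert ss.k_states == 6
        assert ss.diffuse_mask.tolist() == [False, True, True, True, True, True]

    def test_random_walk_limit_keeps_trend_constant(self):
        ss = build_state_space(ModelSpec(), phi=1.0, sigma2_eta=0.0)
        x = np.array([3.0, 1, 2, 3, 4, 5])
        np.testing.assert_allclose(ss.transition @ x, x)
        assert ss.diffuse_mask[0]

    def test_observation_row_sums_trend_and_harmonics(self):
        ss = build_state_space(ModelSpec())
        for t in (0, 1, 7):
            z = ss.design_row(t)
            assert z[0] == 1.0
            np.testing.assert_allclose(z[1:], harmonic_design(np.array([t]))[0])

    def test_invalid_harmonic_count_rejected(self):
        with pytest.raises(ValueError):
            ModelSpec(n_harmonics=4)


class TestLikelihoodOracle:
    @pytest.mark.parametrize("seed", range(10))
    def test_filter_matches_dense_gaussian_density(self, seed):
        y, params = _random_instance(seed)
        a = kalman_loglik(y, params)
        b = dense_loglik(y, params)
        assert a == pytest.approx(b, rel=1e-10)

    def test_missing_values_reduce_to_observed_subset(self):
        y, params = _random_instance(77, n_missing=0)
        y2 = y.copy()
        y2[5] = np.nan
        assert kalman_loglik(y2, params) == pytest.approx(
            dense_loglik(y2, params), rel=1e-10
        )

    def test_random_walk_diffuse_matches_conditional_density(self):
        y, params = _random_instance(5, n_missing=2, phi=1.0)
        assert kalman_loglik(y, params) == pytest.approx(
            dense_loglik(y, params), rel=1e-10
        )

    def test_scaling_identity(self):
        """Scaling the data and all SD parameters by c shifts the
        log-likelihood by -n log c (Gaussian change of variables)."""
        y, params = _random_instance(11)
        c = 3.7
        scaled = StructuralParams(
            params.phi, params.sigma2_eta * c**2, params.sigma2_eps * c**2,
            params.seasonal * c,
        )
        n_obs = int(np.isfinite(y).sum())
        assert kalman_loglik(y * c, scaled) == pytest.approx(
            kalman_loglik(y, params) - n_obs * np.log(c)
        )

    def test_all_missing_rejected(self):
        y, params = _random_instance(1, n_missing=0)
        with pytest.raises(ValueError):
            kalman_loglik(np.full_like(y, np.nan), params)

    def test_nonfinite_parameters_rejected(self):
        y, params = _random_instance(2)
        bad = StructuralParams(0.5, 1.0, 1.0, params.seasonal)
        object.__setattr__(bad, "sigma2_eps", np.inf)
        with pytest.raises(ValueError):
            kalman_loglik(y, bad)


class TestSmootherOracle:
    @pytest.mark.parametrize("seed", [3, 21, 60])
    def test_smoothed_trend_equals_gls_projection(self, seed):
        from copetrend.structural import _smooth_trend

        y, params = _random_instance(seed, n=24, n_missing=4)
        obs = np.isfinite(y)
        X = harmonic_design(np.arange(len(y)))
        z = np.where(obs, y - X @ params.seasonal, np.nan)
        mu_filter = _smooth_trend(z, obs, params.phi, params.sigma2_eta,
                                  params.sigma2_eps)
        mu_dense = dense_smoothed_trend(y, params)
        np.testing.assert_allclose(mu_filter, mu_dense, atol=1e-8)


class TestFit:
    def test_zero_noise_recovery(self):
        beta = np.array([50.0, 30.0, 10.0, -5.0, 8.0])
        y = 200.0 + harmonic_design(np.arange(198)) @ beta
        f = fit(make_series(y))
        assert f.converged
        assert np.max(np.abs(f.fitted - y)) < 1e-6
        assert f.sigma2_eps < 1e-6

    def test_constant_series(self):
        f = fit(make_series(np.full(198, 42.0)))
        np.testing.assert_allclose(f.mu, 42.0, atol=1e-8)
        np.testing.assert_allclose(f.gamma, 0.0, atol=1e-8)

    def test_seasonal_is_periodic_and_zero_mean(self):
        rng = np.random.default_rng(0)
        params = StructuralParams(0.9, 4.0, 25.0, np.array([30.0, 10.0, 5.0, 0.0, 2.0]))
        y = simulate_structural(120, params, rng)
        f = fit(make_series(y))
        g = f.gamma
        np.testing.assert_allclose(g[6:], g[:-6], atol=1e-8)
        for k in range(len(g) - 6):
            assert abs(g[k:k + 6].sum()) < 1e-6

    def test_optimum_dominates_every_start(self):
        rng = np.random.default_rng(14)
        params = StructuralParams(0.9, 4.0, 25.0, np.array([30.0, 10.0, 0, 0, 0]))
        y = simulate_structural(96, params, rng)
        f = fit(make_series(y))
        assert f.loglik >= max(f.tried_logliks) - 1e-8

    def test_short_series_rejected(self):
        y = np.full(18, 5.0)
        with pytest.raises(ValueError, match="24"):
            fit(make_series(y))

    def test_error_ar1_variant_runs_and_is_labeled(self):
        rng = np.random.default_rng(3)
        params = StructuralParams(0.8, 2.0, 9.0, np.array([20.0, 5.0, 0, 0, 0]))
        y = simulate_structural(96, params, rng)
        f = fit(make_series(y), ModelSpec(error_ar1=True))
        assert f.spec.error_ar1
        assert np.isfinite(f.loglik)


class TestSplitPeriods:
    def _series_with_gap(self, region):
        vals = np.full(198, 10.0)
        data = pd.DataFrame({
            "year": np.repeat(np.arange(1977, 2010), 6),
            "bin": np.tile(np.arange(1, 7), 33),
            "value": vals, "n_samples": 1,
        })
        data.loc[data.year.between(1989, 1991), "value"] = np.nan
        return AbundanceSeries("X", region, data)

    def test_southern_series_splits_into_72_and_108_bins(self):
        parts = split_periods(self._series_with_gap("MAB"))
        assert [p[0] for p in parts] == ["1977-1988", "1992-2009"]
        assert [len(p[1].data) for p in parts] == [72, 108]

    def test_northern_series_kept_whole(self):
        parts = split_periods(self._series_with_gap("GOM"))
        assert len(parts) == 1 and parts[0][0] == "full"
        assert len(parts[0][1].data) == 198

    def test_series_inside_one_period(self):
        vals = np.full(36, 5.0)
        s = make_series(vals, region="MAB", year0=1980)
        parts = split_periods(s)
        assert len(parts) == 1 and parts[0][0] == "1977-1988"


def test_series_invariants_rejected():
    data = pd.DataFrame({
        "year": [1990, 1990], "bin": [1, 1], "value": [1.0, 2.0], "n_samples": 1,
    })
    with pytest.raises(ValueError):
        AbundanceSeries("X", "GOM", data)
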