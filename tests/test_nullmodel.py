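"""Logistic null-model fitting, simulation and the envelope test."""

import numpy as np
import pytest
from scipy import stats

from paleodem import (
    SPD,
    AnalysisConfig,
    fit_logistic,
    model_test,
    simulate_spd_under_model,
)
from paleodem.errors import ValidationError
from paleodem.nullmodel import (
    LogisticFit,
    deviation_statistic,
    exceedance_regions,
)

WINDOW = (4600, 3400)


@pytest.fixture(scope="module")
def cfg():
    return AnalysisConfig(analysis_window_cal=WINDOW, nsim=199)


@pytest.fixture(scope="module")
def true_fit():
    return LogisticFit(K=0.1, r=0.004, t_mid=4100.0, rss=0.0, window=WINDOW)


def _spd_from(grid, values):
    return SPD(grid=grid, value=values, meta={"n_bins": 1})


class TestFitLogistic:
    def test_exact_recovery(self, cfg):
        grid = cfg.grid
        truth = LogisticFit(K=1.0, r=0.005, t_mid=4000.0, rss=0.0, window=WINDOW)
        fit = fit_logistic(_spd_from(grid, truth.curve(grid)))
        assert fit.K == pytest.approx(1.0, rel=0.01)
        assert fit.r == pytest.approx(0.005, rel=0.01)
        assert fit.t_mid == pytest.approx(4000.0, abs=5)

    def test_recovery_under_one_percent_noise(self, cfg, rng):
        grid = cfg.grid
        truth = LogisticFit(K=1.0, r=0.005, t_mid=4000.0, rss=0.0, window=WINDOW)
        y = truth.curve(grid) * (1.0 + 0.01 * rng.normal(size=grid.size))
        fit = fit_logistic(_spd_from(grid, y))
        assert fit.K == pytest.approx(1.0, rel=0.10)
        assert fit.r == pytest.approx(0.005, rel=0.10)
        assert fit.t_mid == pytest.approx(4000.0, abs=60)

    def test_constant_spd_flags_boundary(self, cfg):
        fit = fit_logistic(_spd_from(cfg.grid, np.full(cfg.grid.size, 0.5)))
        assert fit.boundary or fit.r < 1e-4

    def test_all_zero_spd_rejected(self, cfg):
        with pytest.raises(ValidationError):
            fit_logistic(_spd_from(cfg.grid, np.zeros(cfg.grid.size)))


class TestSimulate:
    def test_mean_of_simulations_tracks_model(self, cfg, true_fit, synth_curve, rng):
        pool = np.full(50, 30.0)
        mean = np.zeros(cfg.grid.size)
        n_rep = 200
        for _ in range(n_rep):
            mean += simulate_spd_under_model(true_fit, 100, pool, synth_curve, cfg, rng).value
        mean /= n_rep
        r, _ = stats.pearsonr(mean, true_fit.curve(cfg.grid))
        assert r > 0.95

    def test_single_bin_mass_is_conserved(self, true_fit, rng):
        from paleodem import identity_curve

        ident = identity_curve(0, 10000, sigma=10.0)
        cfg0 = AnalysisConfig(analysis_window_cal=(6000, 3000), simulation_pad=0)
        fit = LogisticFit(K=1.0, r=0.004, t_mid=4500.0, rss=0.0, window=(6000, 3000))
        spd = simulate_spd_under_model(fit, 1, [25.0], ident, cfg0, rng)
        assert spd.mass == pytest.approx(1.0, abs=0.02)

    def test_fixed_seed_reproduces_bitwise(self, cfg, true_fit, synth_curve):
        pool = [20.0, 30.0, 45.0]
        a = simulate_spd_under_model(true_fit, 40, pool, synth_curve, cfg, np.random.default_rng(7))
        b = simulate_spd_under_model(true_fit, 40, pool, synth_curve, cfg, np.random.default_rng(7))
        np.testing.assert_array_equal(a.value, b.value)


class TestModelTest:
    def test_null_data_not_rejected_small_study(self, cfg, true_fit, synth_curve):
        # small-scale sanity version of the type-I study (the full
        # 100-replicate calibration lives in the acceptance suite)
        rejections = 0
        pool = np.full(40, 30.0)
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            obs = simulate_spd_under_model(true_fit, 60, pool, synth_curve, cfg, rng)
            res = model_test(obs, synth_curve, pool, cfg, rng, nsim=99)
            rejections += res.global_p <= 0.05
        assert rejections <= 2

    def test_inserted_boom_is_detected(self, cfg, true_fit, synth_curve):
        rng = np.random.default_rng(7)
        pool = np.full(40, 30.0)
        obs = simulate_spd_under_model(true_fit, 80, pool, synth_curve, cfg, rng)
        boom = (obs.grid <= 4200) & (obs.grid > 3900)
        obs.value[boom] *= 3.0
        i0 = int(obs.ext_grid[0] - obs.grid[0])
        obs.ext_value[i0 : i0 + obs.grid.size] = obs.value
        res = model_test(obs, synth_curve, pool, cfg, rng, nsim=999)
        assert res.global_p <= 0.01
        assert any(a >= 3900 and b <= 4200 for a, b in res.positive_regions)

    def test_too_few_simulations_refused(self, cfg, synth_curve, true_fit, rng):
        obs = simulate_spd_under_model(true_fit, 10, [30.0], synth_curve, cfg, rng)
        with pytest.raises(ValidationError):
            model_test(obs, synth_curve, [30.0], cfg, rng, nsim=10)

    def test_global_p_bounds_and_monotonicity(self):
        lo = np.zeros(5)
        hi = np.ones(5)
        s_small = deviation_statistic(np.full(5, 1.1), lo, hi)
        s_large = deviation_statistic(np.full(5, 2.0), lo, hi)
        assert 0 < s_small < s_large
        sims = np.array([0.1, 0.2, 0.3, 0.7])
        p_small = (1 + np.sum(sims >= s_small)) / (len(sims) + 1)
        p_large = (1 + np.sum(sims >= s_large)) / (len(sims) + 1)
        assert p_large <= p_small

    def test_degenerate_envelope_gives_p_one(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert deviation_statistic(obs, obs, obs) == 0.0
        pos, neg = exceedance_regions(np.array([5000, 4999, 4998]), obs, obs, obs)
        assert pos == [] and neg == []

    def test_exceedance_regions_are_maximal_intervals(self):
        grid = np.arange(5000, 4990, -1)
        obs = np.array([0, 5, 5, 0, 0, 5, 0, 0, 5, 5], dtype=float)
        hi = np.ones(10)
        pos, neg = exceedance_regions(grid, obs, np.zeros(10) - 1, hi)
        assert pos == [(4999.0, 4998.0), (4995.0, 4995.0), (4992.0, 4991.0)]
        assert neg == []

    def test_envelope_widens_with_fewer_bins(self, cfg, true_fit, synth_curve):
        pool = np.full(50, 30.0)
        widths = {}
        for n_bins in (20, 200):
            rng = np.random.default_rng(1)
            sims = np.array(
                [
                    simulate_spd_under_model(true_fit, n_bins, pool, synth_curve, cfg, rng).value
                    for _ in range(100)
                ]
            )
            lo, hi = np.percentile(sims, 2.5, axis=0), np.percentile(sims, 97.5, axis=0)
            widths[n_bins] = float(((hi - lo) / np.maximum(sims.mean(axis=0), 1e-12)).mean())
        assert widths[20] > widths[200]
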