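"""Growth-kinetics operations against brute-force and generator oracles."""

import warnings

import numpy as np
import pytest

from mixcult.config import ExperimentConfig
from mixcult.growth import (
    UndefinedFitError,
    estimate_blank_absorbance,
    estimate_blank_fluorescence,
    growth_rate,
    growth_yield,
    lag_time,
    pathlength_correct,
    rolling_rate,
    select_fit_window,
    smooth_and_truncate,
    theil_sen_loglinear,
)
from mixcult.pipeline import fit_growth
from mixcult.synthetic import ReadoutParams, StrainParams, default_time_grid, simulate_plate


def brute_force_theil_sen(t, y):
    """Median over all pairwise slopes; the textbook definition."""
    slopes = [
        (y[j] - y[i]) / (t[j] - t[i])
        for i in range(len(t))
        for j in range(i + 1, len(t))
        if t[j] != t[i]
    ]
    slope = np.median(slopes)
    return slope, np.median(y) - slope * np.median(t)


def windowed_mean_oracle(values, window):
    """Direct centered rolling mean with truncated edge windows."""
    half = window // 2
    n = len(values)
    return np.array(
        [np.mean(values[max(0, i - half) : min(n, i + half + 1)]) for i in range(n)]
    )


class TestPreprocessing:
    def test_pathlength_correction(self):
        assert pathlength_correct(0.28, 0.56) == pytest.approx(0.5)
        np.testing.assert_allclose(pathlength_correct([0.1, 0.2], 1.0), [0.1, 0.2])
        with pytest.raises(ValueError):
            pathlength_correct([0.1], 0.0)

    def test_blank_absorbance(self):
        assert estimate_blank_absorbance([0.110, 0.112, 0.2], 0.01) == pytest.approx(0.101)
        assert estimate_blank_absorbance([0.110, 0.112], 0.0) == pytest.approx(0.111)
        with pytest.raises(ValueError):
            estimate_blank_absorbance([0.1], 0.01)

    def test_blank_fluorescence(self):
        wells = {"A1": np.full(5, 50.0), "B1": np.full(5, 50.0), "C1": np.full(5, 900.0)}
        assert estimate_blank_fluorescence(wells, marker_wells={"C1"}) == pytest.approx(50.0)
        with pytest.raises(ValueError, match="no marker-free"):
            estimate_blank_fluorescence(wells, marker_wells={"A1", "B1", "C1"})


class TestSmoothing:
    def test_constant_series_unchanged(self):
        t = np.arange(10.0)
        _, v = smooth_and_truncate(t, np.full(10, 3.0), horizon=100.0)
        np.testing.assert_allclose(v, 3.0)

    def test_matches_direct_windowed_mean(self):
        # [ORACLE] explicit truncated-window means, including the edges
        rng = np.random.default_rng(0)
        t = np.arange(30.0)
        y = rng.normal(size=30)
        _, v = smooth_and_truncate(t, y, window=7, horizon=100.0)
        np.testing.assert_allclose(v, windowed_mean_oracle(y, 7), rtol=1e-12)

    def test_truncation_to_horizon(self):
        t = np.arange(0, 60.1, 1 / 6)
        tt, _ = smooth_and_truncate(t, np.ones_like(t), horizon=24.0)
        assert tt.max() <= 24.0 + 1e-9
        with pytest.raises(ValueError):
            smooth_and_truncate([], [], horizon=24.0)
        with pytest.raises(ValueError, match="odd"):
            smooth_and_truncate(t, np.ones_like(t), window=6)


class TestTheilSen:
    def test_exact_exponential(self):
        t = np.linspace(0, 10, 25)
        slope, intercept = theil_sen_loglinear(t, 0.01 * np.exp(0.47 * t))
        assert slope == pytest.approx(0.47, abs=1e-12)
        assert intercept == pytest.approx(np.log(0.01), abs=1e-10)

    def test_outlier_series_matches_brute_force(self):
        # [ORACLE] explicit enumeration of the 10 pairwise slopes
        t = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        a = np.array([1.0, 2.7, 50.0, 20.1, 54.6])
        slope, intercept = theil_sen_loglinear(t, a)
        bf_slope, bf_intercept = brute_force_theil_sen(t, np.log(a))
        assert slope == pytest.approx(bf_slope, rel=1e-12)
        assert intercept == pytest.approx(bf_intercept, rel=1e-12)

    def test_scaling_shifts_intercept_only(self):
        t = np.linspace(0, 8, 20)
        a = 0.01 * np.exp(0.3 * t) * (1 + 0.05 * np.sin(t))
        s1, i1 = theil_sen_loglinear(t, a)
        s2, i2 = theil_sen_loglinear(t, 7.0 * a)
        assert s2 == pytest.approx(s1, rel=1e-12)
        assert i2 - i1 == pytest.approx(np.log(7.0), rel=1e-12)

    def test_nonpositive_points_dropped(self):
        t = np.linspace(0, 10, 12)
        a = 0.01 * np.exp(0.4 * t)
        a[3] = -1.0
        with pytest.warns(UserWarning, match="non-positive"):
            slope, _ = theil_sen_loglinear(t, a)
        assert slope == pytest.approx(0.4, abs=1e-12)
        with pytest.raises(UndefinedFitError):
            theil_sen_loglinear([1.0, 2.0], [-1.0, -2.0])

    def test_breakdown_resistance(self):
        # replacing <29% of points by arbitrary outliers leaves the rate intact
        t = np.linspace(0, 14, 15)
        a = 0.01 * np.exp(0.47 * t)
        a[[2, 7, 12]] = [5.0, 1e-4, 30.0]  # 20% outliers
        slope, _ = theil_sen_loglinear(t, a)
        assert slope == pytest.approx(0.47, abs=1e-6)


class TestRollingRate:
    def test_exact_exponential_constant_rate(self):
        t = np.arange(0, 24, 1 / 6)
        rr = rolling_rate(t, 0.01 * np.exp(0.47 * t))
        np.testing.assert_allclose(rr[~np.isnan(rr)], 0.47, atol=1e-10)

    def test_lag_then_exponential_matches_windowed_oracle(self):
        t = np.arange(0, 24, 1 / 6)
        a = 0.01 * np.exp(0.5 * np.clip(t - 6.0, 0, None))
        rr = rolling_rate(t, a, window=19, min_window=10)
        # [ORACLE] brute-force Theil-Sen in each truncated window
        half = 19 // 2
        for i in [0, 30, 60, 100, len(t) - 1]:
            lo, hi = max(0, i - half), min(len(t), i + half + 1)
            if hi - lo < 10:
                assert np.isnan(rr[i])
                continue
            exp_slope, _ = brute_force_theil_sen(t[lo:hi], np.log(a[lo:hi]))
            assert rr[i] == pytest.approx(exp_slope, abs=1e-10)
        in_lag = (t > 1.5) & (t < 4.5)
        in_log = (t > 9) & (t < 20)
        assert np.nanmax(np.abs(rr[in_lag])) < 0.05
        np.testing.assert_allclose(rr[in_log], 0.5, atol=1e-8)

    def test_short_series_rejected(self):
        with pytest.raises(UndefinedFitError):
            rolling_rate(np.arange(9.0), np.ones(9), min_window=10)


class TestWindowSelection:
    def test_never_growing_gives_empty_mask(self):
        a = np.full(50, 1e-3)
        assert not select_fit_window(a, mode="fixed").any()

    def test_fixed_mask_matches_analytic_crossings(self):
        # [ORACLE] crossing times solved from a0*exp(mu t) = threshold
        t = np.arange(0, 24, 1 / 6)
        mu, a0 = 0.47, 0.01
        a = a0 * np.exp(mu * t)
        mask = select_fit_window(a, mode="fixed")
        t_lo = np.log(1.5e-2 / a0) / mu
        t_hi = np.log(6e-2 / a0) / mu
        expected = (t > t_lo) & (t < t_hi)
        np.testing.assert_array_equal(mask, expected)

    def test_dynamic_mask_ends_at_last_fast_point(self):
        t = np.arange(0, 24, 1 / 6)
        a = np.minimum(0.01 * np.exp(0.47 * t), 0.3)  # saturating curve
        rr = rolling_rate(t, a)
        mask = select_fit_window(a, mode="dynamic", rolling_rates=rr)
        # [ORACLE] brute-force scan of the rolling-rate output
        fast = np.nonzero(np.nan_to_num(rr, nan=-np.inf) > 0.1)[0]
        start = np.nonzero(a > 1.5e-2)[0][0]
        assert mask[start] and mask[fast[-1]]
        assert not mask[fast[-1] + 1 :].any()
        assert not mask[:start].any()

    def test_dynamic_mode_requires_rolling_rates(self):
        with pytest.raises(ValueError):
            select_fit_window(np.ones(5), mode="dynamic")


class TestGrowthFit:
    def test_thin_window_sets_rate_zero(self):
        t = np.arange(0, 24, 1 / 6)
        fit = growth_rate(t, np.full(t.size, 1e-3), mode="fixed")
        assert fit.rate == 0.0 and fit.lag == -np.inf
        # six in-window points: still zero even though a slope is estimable
        t6 = np.arange(6.0)
        a6 = np.full(6, 0.03)
        fit6 = growth_rate(t6, 0.02 * np.exp(0.1 * t6), mode="fixed", rolling_min_window=2)
        assert fit6.n_points_used < 7 and fit6.rate == 0.0

    def test_exact_exponential_rate_and_lag(self):
        t = np.arange(0, 24, 1 / 6)
        a0 = 0.01
        fit = growth_rate(t, a0 * np.exp(0.47 * t), mode="fixed")
        assert fit.rate == pytest.approx(0.47, abs=1e-10)
        assert lag_time(fit, a0) == pytest.approx(0.0, abs=1e-9)

    def test_injected_lag_recovered(self):
        t = np.arange(0, 24, 1 / 6)
        a = 0.01 * np.exp(0.47 * np.clip(t - 5.0, 0, None))
        rrfit = growth_rate(t, a, mode="fixed")
        assert lag_time(rrfit, 0.01) == pytest.approx(5.0, abs=1 / 6)

    def test_nongrowing_lag_is_minus_infinity(self):
        fit = growth_rate(np.arange(20.0), np.full(20, 1e-3), mode="fixed")
        assert lag_time(fit, 0.01) == -np.inf

    def test_yield_at_24h(self):
        t = np.arange(0, 24.01, 1 / 6)
        a = np.minimum(0.01 * np.exp(0.5 * t), 0.55)
        assert growth_yield(t, a) == pytest.approx(0.55)
        still = 0.01 * np.exp(0.15 * t)
        assert growth_yield(t, still) == pytest.approx(0.01 * np.exp(0.15 * 24), rel=1e-6)
        with pytest.raises(ValueError):
            growth_yield(t[t < 20], a[t < 20])


class TestPipelineProperties:
    def test_noiseless_channel_concordance(self, ideal_readout):
        # equal-rate strains with a shared lag: all three channels agree
        sal = StrainParams("sal", 0.45, 1.0, 5e-3, 0.3, "CFP")
        dep = StrainParams("dep", 0.45, 1.0, 5e-3, 0.3, "YFP")
        layout = {
            "A1": [sal, dep],
            "B1": [StrainParams("sal", 0.45, 1.0, 1e-2, 0.3, "CFP")],
            "C1": [StrainParams("dep", 0.45, 1.0, 1e-2, 0.3, "YFP")],
        }
        plate = simulate_plate(layout, ideal_readout, default_time_grid(), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = fit_growth(plate, ExperimentConfig())
        rates = fits[fits["well"] == "A1"].set_index("source_channel")["rate"]
        assert rates["A600"] == pytest.approx(0.45, abs=1e-6)
        assert rates["CFP"] == pytest.approx(rates["A600"], abs=1e-6)
        assert rates["YFP"] == pytest.approx(rates["A600"], abs=1e-6)

    def test_scaling_raw_fluorescence_is_neutral_after_recalibration(self, ideal_readout):
        layout = {
            "A1": [
                StrainParams("sal", 0.47, 1.0, 5e-3, 0.4, "CFP"),
                StrainParams("dep", 0.40, 4.0, 5e-3, 0.05, "YFP"),
            ],
            "B1": [StrainParams("sal", 0.47, 1.0, 1e-2, 0.4, "CFP")],
            "C1": [StrainParams("dep", 0.40, 4.0, 1e-2, 0.05, "YFP")],
        }
        plate = simulate_plate(layout, ideal_readout, default_time_grid(), seed=0)
        cfg = ExperimentConfig()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = fit_growth(plate, cfg)
            scaled_plate = plate
            fl = scaled_plate.data["channel"].isin(["CFP", "YFP"])
            scaled_plate.data.loc[fl, "value"] *= 3.7
            scaled = fit_growth(scaled_plate, cfg)
        for col in ("rate", "lag"):
            np.testing.assert_allclose(
                base[base.source_channel != "A600"][col],
                scaled[scaled.source_channel != "A600"][col],
                rtol=1e-9,
            )

    def test_parameter_recovery_grid_under_default_noise(self, default_readout):
        # median error over a (rate, lag) grid with the default noise model
        cfg = ExperimentConfig()
        rate_errs, lag_errs = [], []
        for i, mu in enumerate([0.15, 0.45, 0.7]):
            for j, lag in enumerate([0.0, 4.0, 8.0]):
                s = StrainParams("s", mu, lag, 1e-2, 0.5, "none")
                plate = simulate_plate(
                    {"A1": [s]}, default_readout, default_time_grid(), seed=100 + 10 * i + j
                )
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_growth(plate, cfg).iloc[0]
                rate_errs.append(abs(fit["rate"] - mu))
                lag_errs.append(abs(fit["lag"] - lag))
        assert np.median(rate_errs) <= 0.01
        assert np.median(lag_errs) <= 0.5
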