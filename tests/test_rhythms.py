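"""Tests of detrending, period estimation, harmonic fits and clustering."""

import numpy as np
import pytest
import scipy.signal
import scipy.stats
from statsmodels.tsa.filters.hp_filter import hpfilter

from clockloops.rhythms import (
    AcrophaseSeries,
    AnalysisConfig,
    TimeSeries,
    batch_dominant_periods,
    batch_hp_detrend,
    count_bivariate_clusters,
    dominant_period,
    find_acrophases,
    fit_harmonic,
    fit_harmonic_shared,
    fit_period_histogram,
    hp_detrend,
    hp_lambda,
    instantaneous_periods,
)


def test_timeseries_validation():
    with pytest.raises(ValueError):
        TimeSeries(np.arange(5.0), np.zeros(5))  # too short
    t = np.arange(10.0)
    t[4] += 1e-6
    with pytest.raises(ValueError):
        TimeSeries(t, np.zeros(10))  # non-uniform


class TestHPDetrend:
    def test_lambda_rule(self):
        # 0.05 * 24**4 evaluated directly
        assert hp_lambda(1.0) == pytest.approx(16588.8)
        assert hp_lambda(2.0) == pytest.approx(0.05 * 12**4)

    def test_constant_series_detrends_to_zero(self):
        s = TimeSeries(np.arange(48.0), np.full(48, 3.7))
        out = hp_detrend(s)
        assert np.allclose(out.values, 0.0, atol=1e-8)

    def test_linear_ramp_passes_through_trend(self):
        t = np.arange(0.0, 240.0)
        s = TimeSeries(t, 0.02 * t)
        out = hp_detrend(s)
        interior = out.values[24:-24]
        assert np.abs(interior).max() < 0.01 * (s.values.max() - s.values.min())
        # cross-check against a dense solve of the HP normal equations
        n = t.size
        d2 = np.diff(np.eye(n), 2, axis=0)
        lam = hp_lambda(1.0)
        trend = np.linalg.solve(np.eye(n) + lam * d2.T @ d2, s.values)
        np.testing.assert_allclose(out.values, s.values - trend, atol=1e-8)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        t = np.arange(100.0)
        x, y = rng.standard_normal((2, 100))
        lhs = hp_detrend(TimeSeries(t, x + y)).values
        rhs = hp_detrend(TimeSeries(t, x)).values + hp_detrend(TimeSeries(t, y)).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_batch_matches_statsmodels(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((120, 7))
        out = batch_hp_detrend(vals, dt=1.0)
        for j in range(7):
            cycle, _ = hpfilter(vals[:, j], lamb=hp_lambda(1.0))
            np.testing.assert_allclose(out[:, j], cycle, atol=1e-8)


class TestDominantPeriod:
    def test_pure_tone(self, cosine_series):
        res = dominant_period(cosine_series)
        assert res.rhythmic
        assert abs(res.dominant_period - 24.0) < 0.1

    def test_invariant_to_scale_and_offset(self, cosine_series):
        res0 = dominant_period(cosine_series)
        scaled = TimeSeries(cosine_series.times, 5 * cosine_series.values + 11)
        assert dominant_period(scaled).dominant_period == res0.dominant_period

    def test_constant_series_flagged_nonrhythmic(self):
        s = TimeSeries(np.arange(50.0), np.zeros(50))
        res = dominant_period(s)
        assert not res.rhythmic and np.all(res.power == 0)

    def test_noisy_tone_recovery_rate(self):
        """23 h cosine + unit noise over 12 d: period within 0.5 h in >=95%."""
        t = np.arange(0.0, 12 * 24 + 0.5, 1.0)
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = np.cos(2 * np.pi * t / 23.0) + rng.standard_normal(t.size)
            res = dominant_period(hp_detrend(TimeSeries(t, y)))
            hits += abs(res.dominant_period - 23.0) < 0.5
        assert hits >= 95

    def test_white_noise_concentrates_at_short_periods(self):
        t = np.arange(0.0, 12 * 24 + 0.5, 1.0)
        short = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            res = dominant_period(TimeSeries(t, rng.standard_normal(t.size)))
            short += res.dominant_period < 20.0
        assert short > 25  # majority of seeds

    def test_batch_matches_scipy_argmax(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 120.0)
        vals = rng.standard_normal((t.size, 6))
        vals[:, 0] += 3 * np.cos(2 * np.pi * t / 24)
        cfg = AnalysisConfig()
        batch = batch_dominant_periods(vals, t, cfg)
        for j in range(6):
            res = dominant_period(TimeSeries(t, vals[:, j]), cfg)
            assert batch[j] == pytest.approx(res.dominant_period)


class TestFitHarmonic:
    def test_pure_cosine(self, cosine_series):
        fit = fit_harmonic(cosine_series, 22.0)
        assert fit.a == pytest.approx(1.0, abs=1e-8)
        assert fit.b == pytest.approx(0.0, abs=1e-8)
        assert fit.tau == pytest.approx(24.0, abs=1e-8)
        assert fit.phase == pytest.approx(0.0, abs=1e-8)

    def test_pure_sine_phase(self):
        t = np.arange(0.0, 96.0)
        fit = fit_harmonic(TimeSeries(t, np.sin(2 * np.pi * t / 24)), 25.0)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-8)
        assert fit.phase == pytest.approx(np.pi / 2, abs=1e-8)

    def test_shared_period_across_phase_shifted_copies(self):
        t = np.arange(0.0, 48.5, 2.0)
        tau = 24.53
        series = [
            TimeSeries(t, 1 + 0.8 * np.cos(2 * np.pi * t / tau - ph))
            for ph in (0.0, 1.2, 2.9)
        ]
        tau_shared, fits = fit_harmonic_shared(series, 24.0, fit_offset=True)
        tau_single = fit_harmonic(series[0], 24.0, fit_offset=True).tau
        assert tau_shared == pytest.approx(tau, abs=1e-6)
        assert tau_shared == pytest.approx(tau_single, abs=1e-6)
        assert fits[1].amplitude == pytest.approx(0.8, abs=1e-6)


class TestAcrophases:
    def test_cosine_interior_peaks(self):
        t = np.arange(0.0, 72.1, 0.1)
        acros = find_acrophases(TimeSeries(t, np.cos(2 * np.pi * t / 24)))
        # boundary peaks at 0 and 72 are discarded by the half-period edge rule
        np.testing.assert_allclose(acros.peak_times, [24.0, 48.0], atol=0.01)

    def test_translation_equivariance(self):
        t = np.arange(0.0, 240.0, 0.1)
        phi = 0.8
        base = find_acrophases(TimeSeries(t, np.cos(2 * np.pi * t / 24)))
        shifted = find_acrophases(TimeSeries(t, np.cos(2 * np.pi * t / 24 + phi)))
        expected = base.peak_times - phi * 24 / (2 * np.pi)
        keep = (expected > 12) & (expected < 240 - 12)
        np.testing.assert_allclose(shifted.peak_times[: keep.sum()],
                                   expected[keep], atol=0.02)

    def test_jittered_cosine_recovered_within_half_hour(self):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 240.0, 0.5)
        y = np.cos(2 * np.pi * t / 24) + 0.1 * rng.standard_normal(t.size)
        acros = find_acrophases(TimeSeries(t, y), period_hint=24.0)
        truth = np.arange(24.0, 240.0 - 12, 24.0)
        assert acros.peak_times.size == truth.size
        assert np.abs(acros.peak_times - truth).max() < 0.5

    def test_instantaneous_periods(self):
        assert np.array_equal(
            instantaneous_periods(AcrophaseSeries(np.array([0.0, 24.0, 48.0]))),
            [24.0, 24.0],
        )
        with pytest.raises(ValueError):
            instantaneous_periods(AcrophaseSeries(np.array([1.0])))

    def test_nonrhythmic_input_gives_empty_result(self):
        s = TimeSeries(np.arange(50.0), np.zeros(50))
        assert find_acrophases(s).empty


class TestPeriodHistogram:
    def test_t_parameter_recovery(self):
        rng = np.random.default_rng(12)
        sample = scipy.stats.t.rvs(df=5, loc=24.0, scale=0.3, size=2000,
                                   random_state=rng)
        fit = fit_period_histogram(sample)
        assert abs(fit.location - 24.0) < 0.05
        assert abs(fit.scale - 0.3) < 0.05

    def test_symmetric_sample_location_near_median(self):
        rng = np.random.default_rng(2)
        sample = rng.normal(23.5, 0.4, 500)
        fit = fit_period_histogram(sample)
        assert abs(fit.location - np.median(sample)) < 0.05

    def test_robustness_to_outliers_vs_gaussian_mean(self):
        rng = np.random.default_rng(8)
        clean = rng.normal(24.0, 0.3, 500)
        outliers = np.full(25, 40.0)
        sample = np.concatenate([clean, outliers])
        fit = fit_period_histogram(sample)
        assert abs(fit.location - 24.0) < abs(sample.mean() - 24.0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_period_histogram(np.full(100, 24.0))
        with pytest.raises(ValueError):
            fit_period_histogram(np.arange(10.0))


class TestClusterCounting:
    def test_single_repeated_point_is_one_cluster(self):
        pa = np.full(100, 23.0)
        assert count_bivariate_clusters(pa, np.full(100, 24.0)) == 1

    def test_two_separated_clusters(self):
        rng = np.random.default_rng(4)
        a = np.concatenate([rng.normal(5, 0.5, 400), rng.normal(23, 0.3, 400)])
        b = np.concatenate([rng.normal(5, 0.5, 400), rng.normal(24, 0.3, 400)])
        assert count_bivariate_clusters(a, b) == 2

    def test_symmetric_under_channel_swap(self):
        rng = np.random.default_rng(6)
        # four-cluster layout mimicking disjoint single-reporter populations
        a = np.concatenate([rng.normal(5, .5, 300), rng.normal(23, .3, 300),
                            rng.normal(23, .3, 300), rng.normal(5, .5, 300)])
        b = np.concatenate([rng.normal(5, .5, 300), rng.normal(24, .3, 300),
                            rng.normal(5, .5, 300), rng.normal(24, .3, 300)])
        assert count_bivariate_clusters(a, b) == count_bivariate_clusters(b, a)

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            count_bivariate_clusters(np.arange(5.0), np.arange(5.0))
        with pytest.raises(ValueError):
            count_bivariate_clusters(np.arange(20.0), np.arange(10.0))
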