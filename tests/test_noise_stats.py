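"""Spectral and tail exponent estimators, filters, classification."""

import numpy as np
import pytest

from cognoise import synthetic
from cognoise.noise_stats import (
    AnalysisConfig,
    PowerSpectrum,
    analyze_series,
    classify_noise,
    filter_time_estimates,
    fit_spectral_exponent,
    fit_tail_exponent,
    power_spectrum,
    successive_changes,
    tail_model_comparison,
)
from cognoise.readout import IRISeries, TimeEstimateSeries


class TestFilter:
    def test_three_times_target_rule(self):
        s = TimeEstimateSeries(np.array([0.9, 2.9, 3.1]), target=1.0)
        out = filter_time_estimates(s)
        assert np.allclose(out.estimates, [0.9, 2.9])
        assert out.n_removed_ == 1

    def test_boundary_is_strict(self):
        s = TimeEstimateSeries(np.array([3.0, 2.999]), target=1.0)
        out = filter_time_estimates(s)
        assert np.allclose(out.estimates, [2.999])

    def test_all_below_unchanged(self):
        s = TimeEstimateSeries(np.array([0.5, 1.0]), target=1.0)
        assert len(filter_time_estimates(s)) == 2

    def test_empty_ok(self):
        s = TimeEstimateSeries(np.empty(0), target=1.0)
        assert len(filter_time_estimates(s)) == 0


class TestSuccessiveChanges:
    def test_small_example(self):
        assert np.allclose(successive_changes([1, 3, 2]), [2, 1])

    def test_constant_series_all_zero(self):
        assert np.all(successive_changes([4.0] * 10) == 0)

    def test_matches_loop_oracle(self, rng):
        x = rng.normal(0, 1, 100)
        expected = [abs(x[i + 1] - x[i]) for i in range(99)]
        assert np.allclose(successive_changes(x), expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            successive_changes([1.0])


class TestPowerSpectrum:
    def test_parseval(self, rng):
        x = rng.normal(0, 2, 1024)
        spec = power_spectrum(x, window_len=1024)
        total = spec.power.sum() / 1024  # integrate density over df = 1/N
        assert total == pytest.approx(x.var(), rel=0.01)

    def test_sinusoid_peak_location(self):
        n = 512
        x = np.sin(2 * np.pi * 0.25 * np.arange(n))
        spec = power_spectrum(x, window_len=256)
        assert spec.freqs[np.argmax(spec.power)] == pytest.approx(0.25, abs=1 / 256)

    def test_single_window_matches_naive_dft(self, rng):
        x = rng.normal(0, 1, 256)
        spec = power_spectrum(x, window_len=256)
        # naive periodogram oracle
        xd = x - x.mean()
        dft = np.fft.rfft(xd)
        pxx = (np.abs(dft) ** 2) / 256
        pxx[1:-1] *= 2  # one-sided density, fs = 1
        assert np.allclose(spec.power, pxx[1:], atol=1e-10)

    def test_too_short_rejected(self, rng):
        with pytest.raises(ValueError):
            power_spectrum(rng.normal(0, 1, 10), window_len=16)

    def test_window_count(self, rng):
        spec = power_spectrum(rng.normal(0, 1, 1024), window_len=256, overlap=0.5)
        assert spec.n_windows == 7


class TestSpectralExponent:
    def test_exact_power_law_recovered_to_machine_precision(self):
        freqs = np.linspace(1 / 2048, 0.5, 1024)
        spec = PowerSpectrum(freqs, freqs ** (-1.3), n_windows=1)
        fit = fit_spectral_exponent(spec, f_max=0.1)
        assert fit.alpha == pytest.approx(1.3, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_flat(self):
        alphas = [
            fit_spectral_exponent(
                power_spectrum(np.random.default_rng(s).normal(0, 1, 1024))
            ).alpha
            for s in range(20)
        ]
        assert abs(np.mean(alphas)) <= 0.2

    @pytest.mark.parametrize("alpha", [0.5, 1.0, 1.5])
    def test_spectral_synthesis_round_trip(self, alpha):
        est = [
            fit_spectral_exponent(power_spectrum(synthetic.gen_fgn(1024, alpha, s))).alpha
            for s in range(20)
        ]
        assert abs(np.mean(est) - alpha) <= 0.15

    def test_log_base_invariance(self):
        """alpha is a slope ratio, so the log base cancels; the natural-log
        fit must agree with the base-10 fit."""
        spec = power_spectrum(synthetic.gen_fgn(1024, 1.0, 3))
        fit10 = fit_spectral_exponent(spec)
        sel = (spec.freqs < 0.1) & (spec.power > 0)
        coef = np.polyfit(np.log(spec.freqs[sel]), np.log(spec.power[sel]), 1)
        # unbinned natural-log slope is close; binning differences are small
        assert fit10.alpha == pytest.approx(-coef[0], abs=0.25)

    def test_too_few_bins_rejected(self):
        spec = PowerSpectrum(np.array([0.2, 0.3, 0.4]), np.ones(3), 1)
        with pytest.raises(ValueError):
            fit_spectral_exponent(spec, f_max=0.1)


class TestTailExponent:
    def test_hill_closed_form(self):
        """If every ln(x/xmin) equals 1, the MLE is exactly mu = 2."""
        x = np.full(50, np.e)
        fit = fit_tail_exponent(x, xmin=1.0)
        assert fit.mu == pytest.approx(2.0, abs=1e-12)

    @pytest.mark.parametrize("mu,tol", [(2.0, 0.1), (2.5, 0.15)])
    def test_pareto_round_trip(self, mu, tol):
        est = [fit_tail_exponent(synthetic.gen_pareto(5000, mu, 1.0, s)).mu for s in range(20)]
        assert abs(np.mean(est) - mu) <= tol

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            fit_tail_exponent(np.ones(5) * 2)

    def test_xmin_recovers_true_cutoff_region(self):
        """Mixture of noise below 1 and Pareto above 1: chosen xmin should
        land near the true cutoff."""
        rng = np.random.default_rng(0)
        body = rng.uniform(0.05, 1.0, 2000)
        tail = synthetic.gen_pareto(2000, 2.0, 1.0, 1)
        fit = fit_tail_exponent(np.concatenate([body, tail]))
        assert 0.5 <= fit.xmin <= 2.0
        assert abs(fit.mu - 2.0) < 0.25


class TestTailComparison:
    def test_pareto_favors_power_law(self):
        wins = 0
        for s in range(20):
            x = synthetic.gen_pareto(2000, 2.0, 1.0, s)
            fit = fit_tail_exponent(x)
            wins += fit.lr_stat > 0 and fit.lr_p < 0.05
        assert wins >= 18

    def test_exponential_favors_exponential(self):
        wins = 0
        for s in range(20):
            x = np.random.default_rng(s).exponential(1.0, 2000)
            stat, _ = tail_model_comparison(x, float(np.quantile(x, 0.2)))
            wins += stat < 0
        assert wins >= 18

    def test_statistic_well_formed(self, rng):
        x = np.concatenate([rng.exponential(1, 500), synthetic.gen_pareto(500, 2.0, 1.0, 4)])
        stat, p = tail_model_comparison(x, 1.0)
        assert np.isfinite(stat)
        assert 0.0 <= p <= 1.0

    def test_degenerate_tail_rejected(self):
        with pytest.raises(ValueError):
            tail_model_comparison(np.full(20, 3.0), 1.0)


class TestClassification:
    @pytest.mark.parametrize(
        "alpha,mu,f_flag,h_flag",
        [
            (0.68, 1.80, True, True),
            (0.38, 2.0, False, True),
            (0.5, 1.0, True, False),   # mu boundary is open at 1
            (1.5, 3.0, True, True),    # closed at alpha=1.5 and mu=3
            (1.51, 3.01, False, False),
            (0.49, 2.0, False, True),
        ],
    )
    def test_boundaries_as_printed(self, alpha, mu, f_flag, h_flag):
        c = classify_noise(alpha, mu)
        assert c.is_one_over_f is f_flag
        assert c.is_heavy_tailed is h_flag

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            classify_noise(np.nan, 2.0)


class TestAnalyzeSeries:
    def test_composition_equals_stages(self):
        rng = np.random.default_rng(5)
        est = np.abs(rng.normal(1.0, 0.2, 600)) + 0.01
        series = TimeEstimateSeries(est, target=1.0)
        spec_fit, tail_fit, cls = analyze_series(series, "timing")
        filtered = filter_time_estimates(series)
        spec2 = fit_spectral_exponent(power_spectrum(filtered.estimates))
        assert spec_fit.alpha == pytest.approx(spec2.alpha)
        ch = successive_changes(filtered.estimates)
        tail2 = fit_tail_exponent(ch[ch > 0])
        assert tail_fit.mu == pytest.approx(tail2.mu)
        assert cls.alpha == pytest.approx(spec_fit.alpha)

    def test_hybrid_fixture_sets_both_flags(self):
        """1/f modulation with power-law jumps: both signatures present."""
        hits = 0
        for s in range(5):
            mod = synthetic.gen_fgn(1024, 1.0, s)
            noise = np.random.default_rng(s + 100).gamma(3, 1 / 3, 1024)
            iris = np.exp(1.2 * mod) * noise
            labels = [f"w{i % 2}{i}" for i in range(len(iris))]
            series = IRISeries(iris, labels)
            _, _, cls = analyze_series(series, "naming")
            hits += cls.is_one_over_f and cls.is_heavy_tailed
        assert hits >= 4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            analyze_series(TimeEstimateSeries(np.array([1.0]), 1.0), "timing")

    def test_estimator_bias_shrinks_with_n(self):
        """Consistency: mean absolute error of both estimators decreases
        from n=256 to n=4096."""
        errs_a, errs_m = {}, {}
        for n in (256, 4096):
            a = [
                abs(fit_spectral_exponent(power_spectrum(synthetic.gen_fgn(n, 1.0, s))).alpha - 1.0)
                for s in range(10)
            ]
            m = [abs(fit_tail_exponent(synthetic.gen_pareto(n, 2.0, 1.0, s)).mu - 2.0) for s in range(10)]
            errs_a[n], errs_m[n] = np.mean(a), np.mean(m)
        assert errs_a[4096] < errs_a[256]
        assert errs_m[4096] < errs_m[256]


class TestNegativeControls:
    def test_levy_flight_heavy_but_uncorrelated(self):
        hits = 0
        for s in range(20):
            steps, pos = synthetic.gen_levy_flight(2000, 2.0, s)
            fit = fit_tail_exponent(steps)
            alpha = fit_spectral_exponent(power_spectrum(steps)).alpha
            cls = classify_noise(alpha, fit.mu)
            hits += cls.is_heavy_tailed and abs(alpha) <= 0.2
        assert hits >= 18

    def test_integrated_noise_changes_are_gaussian_not_heavy(self):
        hits = 0
        for s in range(20):
            traj = synthetic.gen_fbm(1024, 1.0, s)
            ch = successive_changes(traj)
            fit = fit_tail_exponent(ch[ch > 0])
            hits += not classify_noise(1.0, fit.mu).is_heavy_tailed
        assert hits >= 18
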