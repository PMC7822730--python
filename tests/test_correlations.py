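"""DLS/NSE fitting: cumulants, exponential fits, KWW, Stokes–Einstein."""

import math

import numpy as np
import pytest

from crowdscatter.correlations import (
    Correlogram,
    ISFCurve,
    band_average_diffusion,
    cumulant_fit,
    double_stretched_fit,
    kd_regression,
    kww_mean_time,
    nse_initial_slope,
    plateau_region,
    rate_to_diffusion,
    scattering_vector,
    single_exponential_fit,
    stokes_einstein_diffusion,
    stokes_einstein_radius,
    truncation_scan,
)
from crowdscatter.schulz import SchulzDistribution
from crowdscatter.synth import GroundTruth, synth_dls_correlogram, synth_two_mode_correlogram


def _mono_correlogram(rate=0.016, n=150, noise=0.0, seed=0, contrast=0.95):
    rng = np.random.default_rng(seed)
    t = np.geomspace(0.1, 2000.0, n)
    g1 = np.exp(-rate * t)
    g2 = 1.0 + contrast * g1**2
    sigma = np.maximum(noise * (g1**2 + 0.05), 1e-6)
    return Correlogram(t, g2 + rng.standard_normal(n) * sigma * (noise > 0), sigma,
                       q=0.0229)


class TestScatteringVector:
    def test_study_geometry(self):
        # θ = 120°, λ = 632.8 nm, n = 1.33 → q = 0.023 nm⁻¹
        q = scattering_vector(120.0, 632.8, 1.33)
        assert q == pytest.approx(0.0229, abs=2e-4)

    def test_right_angle(self):
        assert scattering_vector(90.0, 632.8, 1.33) == pytest.approx(0.01868, abs=2e-5)

    def test_small_angle_limit(self):
        assert scattering_vector(1e-6, 632.8, 1.33) == pytest.approx(0.0, abs=1e-9)

    def test_invalid_angle(self):
        with pytest.raises(ValueError):
            scattering_vector(190.0, 632.8, 1.33)


class TestCumulantFit:
    def test_single_exponential_gives_zero_width(self):
        corr = _mono_correlogram()
        fit = cumulant_fit(corr, 200.0)
        assert fit.sigma_star < 0.02
        assert fit.mean_rate == pytest.approx(0.016, rel=1e-3)

    def test_contrast_invariance(self):
        # rate and σ* must not depend on the speckle contrast
        fits = [
            cumulant_fit(_mono_correlogram(contrast=a), 200.0) for a in (0.3, 0.95)
        ]
        assert fits[0].mean_rate == pytest.approx(fits[1].mean_rate, rel=1e-6)

    def test_recovers_rate_spread_of_schulz_ensemble(self, dls_truth):
        # the cumulant width measures the intensity-weighted spread of decay
        # RATES (∝ 1/R), which for a Schulz ensemble with R⁶ weighting is
        # 1/sqrt(1/σ*² + 4) — narrower than the radius spread σ*
        c = 1.0 / dls_truth.distribution.sigma_star**2
        rate_spread = 1.0 / math.sqrt(c + 4.0)
        corr = synth_dls_correlogram(dls_truth, noise=0.0, seed=1)
        tau0 = 1.0 / cumulant_fit(corr, 60.0).mean_rate
        fit = cumulant_fit(corr, 0.35 * tau0)
        assert fit.sigma_star == pytest.approx(rate_spread, rel=0.08)

    def test_needs_enough_points(self):
        corr = _mono_correlogram()
        with pytest.raises(ValueError):
            cumulant_fit(corr, corr.lag_times[3])


class TestNonergodicDetection:
    def test_ergodic_sample_not_flagged(self):
        from crowdscatter.correlations import is_nonergodic

        assert not is_nonergodic(_mono_correlogram())

    def test_low_intercept_flagged(self):
        from crowdscatter.correlations import is_nonergodic

        t = np.geomspace(0.1, 2000.0, 100)
        g2 = 1.0 + 0.15 * np.exp(-2.0 * 0.016 * t)  # frozen-in speckle
        corr = Correlogram(t, g2, np.full(100, 1e-3), q=0.0229)
        assert is_nonergodic(corr)

    def test_drifting_baseline_flagged(self):
        from crowdscatter.correlations import is_nonergodic

        t = np.geomspace(0.1, 2000.0, 100)
        g2 = 1.1 + 0.9 * np.exp(-2.0 * 0.016 * t)  # never decays to 1
        corr = Correlogram(t, g2, np.full(100, 1e-3), q=0.0229)
        assert is_nonergodic(corr)


class TestTruncationScan:
    def test_clean_data_plateaus_over_full_range(self, dls_truth):
        corr = synth_dls_correlogram(dls_truth, noise=0.0005, seed=2)
        fits = truncation_scan(corr, np.geomspace(80.0, 640.0, 6))
        assert plateau_region(fits, rel_tol=0.15) is not None

    def test_two_mode_data_width_not_truncation_stable(self):
        corr = synth_two_mode_correlogram(
            0.9, 20.0, 1.0, 2e4, 0.7, noise=0.0005, seed=3
        )
        fits = truncation_scan(corr, np.geomspace(10.0, 2e4, 8))
        sig = np.array([f.sigma_star for f in fits])
        # a hidden slow mode leaves no truncation-independent width: the
        # apparent σ* rises as the slow mode enters the window, then drifts
        assert sig.max() > 3.0 * sig.min()
        assert sig.max() > sig[0]

    def test_needs_three_truncations(self):
        corr = _mono_correlogram()
        with pytest.raises(ValueError):
            truncation_scan(corr, [100.0, 200.0])


class TestDiffusionConversions:
    def test_study_numbers(self):
        # 0.01592 µs⁻¹ at q = 0.0229 nm⁻¹ → 3.04e-11 m²/s
        d = rate_to_diffusion(0.01592, 0.0229)
        assert d == pytest.approx(3.04e-11, rel=0.005)

    def test_diffusive_scaling(self):
        assert rate_to_diffusion(0.4, 2.0) == pytest.approx(
            rate_to_diffusion(0.1, 1.0)
        )

    def test_stokes_einstein_study_value(self):
        # D₀ = 3.04e-11 m²/s in D₂O buffer at 25 °C → R_h = 6.5 nm
        rh = stokes_einstein_radius(3.04e-11, 298.15, 1.095)
        assert rh == pytest.approx(6.5, rel=0.02)

    def test_round_trip(self):
        d = stokes_einstein_diffusion(6.5, 298.15, 1.095)
        assert stokes_einstein_radius(d, 298.15, 1.095) == pytest.approx(6.5, rel=1e-12)

    def test_tracer_bead_diffusivity(self):
        # 150 nm tracer in water at 25 °C
        d = stokes_einstein_diffusion(150.0, 298.15, 0.89)
        assert d == pytest.approx(1.63e-12, rel=0.01)


class TestSingleExponential:
    def test_noiseless_exact(self):
        corr = _mono_correlogram(rate=0.02)
        rate, a, b = single_exponential_fit(corr)
        assert rate == pytest.approx(0.02, rel=1e-7)
        assert b == pytest.approx(1.0, abs=1e-6)

    def test_one_percent_noise_two_percent_rate(self):
        rates = []
        for seed in range(20):
            corr = _mono_correlogram(rate=0.02, noise=0.01, seed=seed)
            rates.append(single_exponential_fit(corr)[0])
        assert np.mean(rates) == pytest.approx(0.02, rel=0.02)


class TestKdRegression:
    def test_constant_series_zero_kd(self):
        c = np.array([2.0, 5.0, 10.0, 20.0])
        d = np.full(4, 3.04e-11)
        out = kd_regression(c, d)
        assert abs(out["Kd"]) < 1e-9

    def test_recovers_synthetic_kd(self):
        rng = np.random.default_rng(4)
        c = np.array([2.0, 5.0, 10.0, 20.0, 40.0])
        kd_true = -0.002
        d = 3.0e-11 * (1.0 + kd_true * c) * (1.0 + 0.002 * rng.standard_normal(5))
        out = kd_regression(c, d)
        assert out["Kd"] == pytest.approx(kd_true, rel=0.10)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            kd_regression([5.0, 5.0], [1e-11, 1e-11])


class TestDoubleStretched:
    def test_noiseless_recovery(self):
        corr = synth_two_mode_correlogram(0.5, 10.0, 1.0, 1e4, 0.66, noise=0.0, seed=0)
        fit = double_stretched_fit(corr)
        assert fit.fast_fraction == pytest.approx(0.5, rel=0.05)
        assert fit.tau1 == pytest.approx(10.0, rel=0.05)
        assert fit.tau2 == pytest.approx(1e4, rel=0.05)
        assert fit.alpha2 == pytest.approx(0.66, rel=0.05)
        assert not fit.mode_collapse

    def test_free_alpha1_stays_near_one(self):
        corr = synth_two_mode_correlogram(0.5, 10.0, 1.0, 1e4, 0.66, noise=0.001, seed=1)
        fit = double_stretched_fit(corr, pin_alpha1=False)
        assert fit.alpha1 == pytest.approx(1.0, abs=0.1)

    def test_single_mode_input_flagged(self):
        corr = synth_two_mode_correlogram(1.0, 50.0, 1.0, 5e4, 0.7, noise=0.001, seed=2)
        fit = double_stretched_fit(corr)
        # τ₂ carries no amplitude: either collapse flag or negligible weight
        assert fit.mode_collapse or fit.fast_fraction > 0.95

    def test_narrow_span_rejected(self):
        t = np.geomspace(1.0, 100.0, 50)
        corr = Correlogram(t, 1.0 + 0.9 * np.exp(-t / 10.0) ** 2,
                           np.full(50, 1e-3), q=0.22)
        with pytest.raises(ValueError):
            double_stretched_fit(corr)


class TestKWW:
    @pytest.mark.parametrize(
        "alpha,factor", [(1.0, 1.0), (0.5, 2.0), (2.0 / 3.0, 1.3293)]
    )
    def test_mean_time_values(self, alpha, factor):
        assert kww_mean_time(7.0, alpha) == pytest.approx(7.0 * factor, rel=1e-4)

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            kww_mean_time(1.0, 0.0)


class TestNSE:
    def _isf(self, d_m2s=3.0e-11, q=1.0, noise=0.0, seed=0, tmax=598.0):
        rng = np.random.default_rng(seed)
        t = np.linspace(0.0, tmax, 60)
        rate = d_m2s * q**2 * 1e9
        isf = np.exp(-rate * t)
        sigma = np.maximum(noise * (isf + 0.05), 1e-8)
        vals = isf + rng.standard_normal(60) * sigma * (noise > 0)
        return ISFCurve(t, vals, sigma, q=q)

    def test_exact_recovery(self):
        isf = self._isf()
        tau_s, d = nse_initial_slope(isf)
        assert d == pytest.approx(3.0e-11, rel=1e-6)

    def test_bi_exponential_initial_slope_is_weighted_mean(self):
        # amplitude-weighted mean rate from the short-time series expansion
        # short window: rates·t_max ≪ 1 so the expansion applies
        t = np.linspace(0.0, 10.0, 40)
        r1, r2, w = 0.02, 0.004, 0.6
        isf_vals = w * np.exp(-r1 * t) + (1 - w) * np.exp(-r2 * t)
        isf = ISFCurve(t, isf_vals, np.full(40, 1e-5), q=1.0)
        tau_s, d = nse_initial_slope(isf, t_max=10.5)
        mean_rate = w * r1 + (1 - w) * r2
        assert 1.0 / tau_s == pytest.approx(mean_rate, rel=0.05)

    def test_default_window_is_50ns(self):
        isf = self._isf()
        import inspect

        sig = inspect.signature(nse_initial_slope)
        assert sig.parameters["t_max"].default == 50.0

    def test_needs_early_points(self):
        t = np.linspace(100.0, 500.0, 30)
        isf = ISFCurve(t, np.exp(-0.01 * t), np.full(30, 1e-3), q=1.0)
        with pytest.raises(ValueError):
            nse_initial_slope(isf)


class TestBandAverage:
    def test_constant_profile(self):
        q = np.linspace(1.0, 3.0, 10)
        d = np.full(10, 2.0e-11)
        e = np.full(10, 1e-12)
        mean, err = band_average_diffusion(q, d, e, (1.8, 2.2))
        assert mean == pytest.approx(2.0e-11)

    def test_weighting_favors_precise_point(self):
        mean, _ = band_average_diffusion(
            [1.9, 2.0], [1.0e-11, 3.0e-11], [1e-13, 1e-12], (1.8, 2.2)
        )
        # hand-computed inverse-variance weights: (100·1 + 1·3)/101
        assert mean == pytest.approx((100.0 * 1.0e-11 + 3.0e-11) / 101.0, rel=1e-9)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            band_average_diffusion([1.0], [1e-11], [1e-12], (1.8, 2.2))
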