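"""Censored moment fitting and the per-intensity error profile."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate
from scipy.stats import norm, weibull_min

from clipcorrect.censored import (
    CensoredGaussian,
    CensoredWeibull,
    _censored_ratio,
    _lower_error_closed,
    error_profile,
    fit_censored_gaussian_moments,
    fit_censored_weibull_moments,
    lower_pixel_error,
    object_error,
    upper_pixel_error,
)
from clipcorrect.exceptions import InfeasibleError, InsufficientDataError
from clipcorrect.simulate import AcquisitionConfig, simulate_scan_stack

from conftest import gradient_truth


class TestCensoredGaussianFit:
    def test_uncensored_sample_reduces_to_plain_moments(self):
        sample = [100, 102, 98, 101, 99, 100, 103, 97]
        fit = fit_censored_gaussian_moments(sample, 255.0)
        assert fit.mu == pytest.approx(100.0)
        assert fit.sigma == pytest.approx(np.std(sample, ddof=1))

    @pytest.mark.parametrize("mu,sigma", [(250.0, 10.0), (240.0, 15.0), (260.0, 8.0)])
    def test_recovery_from_large_censored_sample(self, mu, sigma, rng):
        x = np.minimum(rng.normal(mu, sigma, 100_000), 255.0)
        fit = fit_censored_gaussian_moments(x, 255.0)
        assert fit.mu == pytest.approx(mu, rel=0.01)
        assert fit.sigma == pytest.approx(sigma, rel=0.01)

    def test_fully_censored_sample_is_infeasible(self):
        with pytest.raises(InfeasibleError):
            fit_censored_gaussian_moments([255.0] * 8, 255.0)

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_censored_gaussian_moments([100.0], 255.0)

    def test_moment_ratio_is_strictly_monotone(self):
        alpha = np.linspace(-12.0, 12.0, 500)
        assert np.all(np.diff(_censored_ratio(alpha)) > 0)


class TestUpperPixelError:
    def test_negligible_tail_mass(self):
        assert upper_pixel_error(CensoredGaussian(100.0, 5.0), 255.0) < 1e-12

    def test_mean_at_threshold(self):
        # U = sigma / sqrt(2*pi) when mu = c_a
        u = upper_pixel_error(CensoredGaussian(255.0, 10.0), 255.0)
        assert u == pytest.approx(3.98942, abs=1e-5)

    def test_closed_form_matches_numeric_integral(self):
        u = upper_pixel_error(CensoredGaussian(250.0, 10.0), 255.0)
        oracle, _ = integrate.quad(
            lambda x: (x - 255.0) * norm.pdf(x, 250.0, 10.0), 255.0, np.inf
        )
        assert u == pytest.approx(oracle, abs=1e-9)
        assert u == pytest.approx(1.978, abs=1e-3)

    @given(
        mu=st.floats(150.0, 280.0),
        sigma=st.floats(1.0, 30.0),
        bump=st.floats(0.1, 20.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_location_and_scale(self, mu, sigma, bump):
        base = upper_pixel_error(CensoredGaussian(mu, sigma), 255.0)
        assert upper_pixel_error(CensoredGaussian(mu + bump, sigma), 255.0) >= base
        assert upper_pixel_error(CensoredGaussian(mu, sigma + bump), 255.0) >= base - 1e-12


class TestCensoredWeibullFit:
    def test_uncensored_sample_reduces_to_plain_method_of_moments(self, rng):
        x = weibull_min.rvs(2.5, scale=80.0, size=50_000, random_state=rng)
        c_b = float(x.min()) - 1.0  # nothing censored
        fit = fit_censored_weibull_moments(x, c_b)
        # plain method of moments: scale ties the mean to Gamma(1 + 1/k)
        from scipy.special import gamma as G

        m, v = x.mean(), x.var(ddof=1)
        assert fit.scale * G(1 + 1 / fit.shape) == pytest.approx(m, rel=1e-6)
        assert (v + m**2) / m**2 == pytest.approx(
            G(1 + 2 / fit.shape) / G(1 + 1 / fit.shape) ** 2, rel=1e-6
        )

    @pytest.mark.parametrize("shape,scale,c_b", [(2.0, 50.0, 20.0), (1.0, 50.0, 20.0)])
    def test_recovery_from_large_censored_sample(self, shape, scale, c_b, rng):
        x = weibull_min.rvs(shape, scale=scale, size=100_000, random_state=rng)
        y = np.where(x <= c_b, c_b, x)
        fit = fit_censored_weibull_moments(y, c_b)
        assert fit.shape == pytest.approx(shape, rel=0.02)
        assert fit.scale == pytest.approx(scale, rel=0.02)

    def test_all_censored_sample_is_infeasible(self):
        with pytest.raises(InfeasibleError):
            fit_censored_weibull_moments([0.0] * 8, 0.0)
        with pytest.raises(InfeasibleError):
            fit_censored_weibull_moments([20.0] * 8, 20.0)


class TestLowerPixelError:
    def test_zero_threshold_means_zero_error(self):
        assert lower_pixel_error(CensoredWeibull(2.0, 50.0), 0.0) == 0.0

    def test_exponential_case_has_analytic_value(self):
        # shape 1 is exponential: L = c_b - scale*(1 - exp(-c_b/scale))
        L = lower_pixel_error(CensoredWeibull(1.0, 50.0), 20.0)
        assert L == pytest.approx(20.0 - 50.0 * (1 - np.exp(-0.4)), abs=1e-9)
        assert L == pytest.approx(3.5160, abs=1e-4)

    def test_negligible_mass_below_threshold(self):
        L = lower_pixel_error(CensoredWeibull(20.0, 200.0), 20.0)
        assert L < 1e-6

    @pytest.mark.parametrize(
        "shape,scale,c_b", [(0.8, 30.0, 10.0), (2.0, 50.0, 25.0), (3.6, 40.0, 35.0)]
    )
    def test_quadrature_matches_incomplete_gamma_form(self, shape, scale, c_b):
        quad_val = lower_pixel_error(CensoredWeibull(shape, scale), c_b)
        closed = float(_lower_error_closed(shape, scale, c_b))
        assert quad_val == pytest.approx(closed, abs=1e-8)

    @given(c1=st.floats(1.0, 30.0), c2=st.floats(1.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_threshold(self, c1, c2):
        lo, hi = sorted([c1, c2])
        p = CensoredWeibull(2.0, 40.0)
        assert lower_pixel_error(p, hi) >= lower_pixel_error(p, lo) - 1e-12


class TestErrorProfile:
    def test_unclipped_stack_has_zero_profile(self):
        stack = simulate_scan_stack(
            gradient_truth(30.0, 180.0, 96),
            AcquisitionConfig(gain_V=300.0, seed=31),
        )
        prof = error_profile(stack)
        present = prof.n > 0
        assert np.all(prof.E[present] < 0.1)
        assert prof.n_excluded.sum() == 0

    def test_total_error_is_sum_of_components(self):
        stack = simulate_scan_stack(
            gradient_truth(0.0, 290.0, 96),
            AcquisitionConfig(gain_V=400.0, offset_pct=-1.0, seed=32),
        )
        prof = error_profile(stack)
        present = prof.n > 0
        assert np.allclose(prof.E[present], (prof.U + prof.L)[present])
        assert np.all(prof.U[present] >= 0)
        assert np.all(prof.L[present] >= 0)
        assert not prof.reliable[251:].any()

    def test_saturated_levels_are_excluded_not_fatal(self):
        stack = simulate_scan_stack(
            gradient_truth(200.0, 400.0, 64),
            AcquisitionConfig(gain_V=300.0, seed=33),
        )
        prof = error_profile(stack)  # fully saturated pixels exist
        assert prof.n_excluded.sum() > 0
        assert np.isfinite(prof.E[prof.n > 0]).all()

    def test_corrected_average_closer_to_truth_than_observed(self):
        # on clipped levels, observed + U - L must beat observed alone
        from clipcorrect.simulate import average_stack, expected_clipping_error

        truth = gradient_truth(180.0, 280.0, 256)
        cfg = AcquisitionConfig(gain_V=350.0, seed=34)
        stack = simulate_scan_stack(truth, cfg)
        prof = error_profile(stack)
        avg = average_stack(stack).pixels
        k_map = np.rint(avg).astype(int)
        target = truth.mu  # no offset
        corrected = avg + prof.upper_map - prof.lower_map
        clipped_lvls = (prof.U > 0.5) & (prof.n >= 200)
        sel = clipped_lvls[k_map] & prof.valid_map
        assert sel.sum() > 1000
        err_obs = np.abs(avg[sel] - target[sel]).mean()
        err_cor = np.abs(corrected[sel] - target[sel]).mean()
        assert err_cor < err_obs


class TestObjectError:
    def test_uniform_error_passes_through(self):
        err = np.zeros((8, 8))
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:5, 2:5] = 1
        err[mask > 0] = 2.0
        out = object_error(err, mask)
        assert len(out) == 1
        assert out[0].mean_error == pytest.approx(2.0)
        assert out[0].n_pixels == 9

    def test_mean_over_object_pixels(self):
        err = np.zeros((4, 4))
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0:2] = 1
        mask[1, 0:2] = 1
        err[0, 0], err[0, 1], err[1, 0], err[1, 1] = 0.0, 0.0, 4.0, 4.0
        out = object_error(err, mask)
        assert out[0].mean_error == pytest.approx(2.0)

    def test_empty_mask_gives_empty_list(self):
        assert object_error(np.zeros((5, 5)), np.zeros((5, 5), dtype=np.uint8)) == []

    def test_nan_pixels_skipped_but_counted(self):
        err = np.full((3, 3), 3.0)
        err[0, 0] = np.nan
        mask = np.ones((3, 3), dtype=np.uint8)
        out = object_error(err, mask)
        assert out[0].n_pixels == 9
        assert out[0].mean_error == pytest.approx(3.0)
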