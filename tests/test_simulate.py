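"""Simulator: generative model, averaging, ground-truth errors, fixtures."""

import numpy as np
import pytest

from clipcorrect.exceptions import ConfigurationError, GenerationError
from clipcorrect.simulate import (
    AcquisitionConfig,
    GroundTruthField,
    ScanStack,
    average_stack,
    expected_clipping_error,
    make_training_collection,
    simulate_scan_stack,
    synth_embryo_pattern,
    true_clipping_error,
)

from conftest import constant_truth, fixed_sigma_config, gradient_truth


class TestSimulateScanStack:
    def test_noise_free_acquisition_reproduces_truth(self):
        truth = constant_truth(100.0, size=16)
        cfg = AcquisitionConfig(noise_a=0.0, noise_b=0.0, seed=0)
        stack = simulate_scan_stack(truth, cfg)
        assert np.all(stack.frames == 100)

    def test_truth_above_ceiling_saturates_every_frame(self):
        truth = constant_truth(300.0, size=16)
        cfg = fixed_sigma_config(1.0, seed=0)
        stack = simulate_scan_stack(truth, cfg)
        assert np.all(stack.frames == 255)

    def test_clipped_frame_mean_matches_monte_carlo_oracle(self, rng):
        # mu=250, sigma=10: the per-frame mean of clipped values must agree
        # with a direct Monte-Carlo estimate of E[rint(clip(X))]
        truth = constant_truth(250.0, size=112)  # ~1e5 pixels per frame
        cfg = fixed_sigma_config(10.0, seed=3)
        stack = simulate_scan_stack(truth, cfg)
        draws = rng.normal(250.0, 10.0, size=1_000_000)
        clipped = np.rint(np.clip(draws, 0.0, 255.0))
        oracle = clipped.mean()
        se_oracle = clipped.std() / 1000.0
        n_obs = stack.frames.size
        se_obs = 10.0 / np.sqrt(n_obs)
        assert abs(stack.float_frames().mean() - oracle) < 3 * (se_oracle + se_obs)

    def test_offset_subtracts_intensity_units(self):
        truth = constant_truth(100.0, size=8)
        cfg = AcquisitionConfig(
            noise_a=0.0, noise_b=0.0, offset_pct=-2.0, offset_units_per_pct=10.0,
        )
        stack = simulate_scan_stack(truth, cfg)
        assert np.all(stack.frames == 80)

    def test_invalid_n_scans_rejected(self):
        with pytest.raises(ConfigurationError):
            AcquisitionConfig(n_scans=1)

    def test_frames_are_integers_within_range(self):
        truth = gradient_truth(-20.0, 300.0, size=64)
        cfg = AcquisitionConfig(gain_V=400.0, offset_pct=-1.0, seed=5)
        stack = simulate_scan_stack(truth, cfg)
        assert stack.frames.dtype == np.uint8
        assert stack.frames.min() >= 0 and stack.frames.max() <= 255


class TestAverageStack:
    def test_identical_frames_average_to_themselves(self):
        frames = np.full((4, 8, 8), 57, dtype=np.uint8)
        stack = ScanStack(frames=frames, config=AcquisitionConfig(n_scans=4))
        assert np.array_equal(average_stack(stack).pixels, frames[0].astype(float))

    def test_two_point_average(self):
        frames = np.stack([np.zeros((4, 4), np.uint8), np.full((4, 4), 255, np.uint8)])
        stack = ScanStack(frames=frames, config=AcquisitionConfig(n_scans=2))
        assert np.all(average_stack(stack).pixels == 127.5)

    def test_averaging_concentrates_around_truth(self):
        # 8 frames at mu=200, sigma=5: averaged within 3*sigma/sqrt(8) of the
        # truth for at least 99% of pixels (Normal tail bound)
        truth = constant_truth(200.0, size=64)
        stack = simulate_scan_stack(truth, fixed_sigma_config(5.0, seed=8))
        avg = average_stack(stack).pixels
        within = np.abs(avg - 200.0) <= 3 * 5.0 / np.sqrt(8)
        assert within.mean() >= 0.99


class TestTrueClippingError:
    def test_no_mass_near_thresholds_gives_zero_error(self):
        truth = constant_truth(100.0, size=8)
        err = true_clipping_error(truth, fixed_sigma_config(5.0, seed=1), n_mc=20_000)
        assert np.all(err.upper < 1e-6)
        assert np.all(err.lower < 1e-6)
        assert np.all(err.total < 0.2)  # rounding jitter only

    def test_upper_component_at_threshold_matches_closed_form(self):
        # mu = c_a: E[(X-c_a)^+] = sigma/sqrt(2*pi)
        truth = constant_truth(255.0, size=16)
        cfg = fixed_sigma_config(10.0, seed=2)
        err = true_clipping_error(truth, cfg, n_mc=100_000)
        expected = 10.0 / np.sqrt(2 * np.pi)
        assert abs(err.upper.mean() - expected) < 0.05
        closed = expected_clipping_error(truth, cfg)
        assert np.allclose(closed.upper, expected, atol=1e-12)

    def test_lower_component_matches_analytic_partial_expectation(self):
        # after subtracting 20 units, low signal clips at zero; the MC lower
        # component must match sigma*h(-m/sigma) from the Normal model
        truth = constant_truth(25.0, size=16)
        cfg = fixed_sigma_config(6.0, offset_pct=-2.0, offset_units_per_pct=10.0, seed=4)
        err = true_clipping_error(truth, cfg, n_mc=100_000)
        closed = expected_clipping_error(truth, cfg)
        assert np.allclose(err.lower, closed.lower, atol=0.08)

    def test_monte_carlo_agrees_with_closed_form_on_a_gradient(self):
        truth = gradient_truth(200.0, 280.0, size=12)
        cfg = fixed_sigma_config(12.0, seed=6)
        err = true_clipping_error(truth, cfg, n_mc=50_000)
        closed = expected_clipping_error(truth, cfg)
        assert np.allclose(err.upper, closed.upper, atol=0.25)


class TestTrainingCollection:
    def test_one_stack_per_truth_and_grid_point(self):
        truths = [constant_truth(50.0, 8), constant_truth(150.0, 8)]
        stacks = make_training_collection(
            truths, [(500.0, 0.0)], AcquisitionConfig(), seed=9
        )
        assert len(stacks) == 2
        stacks = make_training_collection(
            truths, [(g, 0.0) for g in range(500, 1001, 50)][:10],
            AcquisitionConfig(), seed=9,
        )
        assert len(stacks) == 20

    def test_same_seed_is_bit_identical(self):
        truths = [gradient_truth(0.0, 255.0, 32)]
        grid = [(450.0, 0.0), (500.0, -2.0)]
        a = make_training_collection(truths, grid, AcquisitionConfig(), seed=11)
        b = make_training_collection(truths, grid, AcquisitionConfig(), seed=11)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.frames, s2.frames)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            make_training_collection([constant_truth(10.0, 8)], [], AcquisitionConfig(), 1)


class TestSynthEmbryoPattern:
    def test_single_constant_nucleus_mean(self):
        truth, mask, pattern = synth_embryo_pattern(
            1, (200.0, 200.0), shape=(32, 32), radius=5, seed=0
        )
        assert len(pattern) == 1
        assert pattern["intensity"].iloc[0] == pytest.approx(200.0)

    def test_nucleus_means_span_requested_range(self):
        _, _, pattern = synth_embryo_pattern(100, (10.0, 250.0), shape=(192, 192),
                                             radius=4, seed=1)
        assert len(pattern) == 100
        assert pattern["intensity"].min() >= 10.0 - 1e-9
        assert pattern["intensity"].max() <= 250.0 + 1e-9

    def test_mask_pixel_counts_match_pattern(self):
        from skimage.measure import label, regionprops

        _, mask, pattern = synth_embryo_pattern(30, (10.0, 250.0), shape=(128, 128),
                                                radius=5, seed=2)
        props = regionprops(label(mask > 0, connectivity=2))
        areas = sorted(p.area for p in props)
        assert areas == sorted(pattern["n_pixels"].tolist())

    def test_overflowing_field_raises(self):
        with pytest.raises(GenerationError):
            synth_embryo_pattern(1000, shape=(64, 64), radius=6, seed=0)


def test_truth_field_validation():
    with pytest.raises(ConfigurationError):
        GroundTruthField(mu=np.array([np.nan]).reshape(1, 1))
    with pytest.raises(ConfigurationError):
        GroundTruthField(mu=np.zeros(5))
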