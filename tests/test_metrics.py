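"""Image-quality and consistency metrics against hand-coded oracles."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter

from stainbridge.metrics import (TTestResult, cv_analysis,
                                 identity_extractor, lpips, mse,
                                 paired_t_test, psnr,
                                 radial_power_spectrum, rgb_to_ycbcr, ssim)


def reference_ssim_windowed(a, b, data_range):
    """Direct transcription of the windowed structural-similarity formula
    (Gaussian window 11x11, sigma 1.5, sample moments via filtering);
    written independently of the implementation under test."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    # truncated Gaussian window identical to an 11-tap kernel
    blur = lambda x: gaussian_filter(x, 1.5, truncate=3.5, mode="reflect")
    mu_a, mu_b = blur(a), blur(b)
    s_aa = blur(a * a) - mu_a**2
    s_bb = blur(b * b) - mu_b**2
    s_ab = blur(a * b) - mu_a * mu_b
    num = (2 * mu_a * mu_b + c1) * (2 * s_ab + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (s_aa + s_bb + c2)
    ssim_map = num / den
    pad = 5
    return ssim_map[pad:-pad, pad:-pad].mean()


class TestSSIM:
    def test_fixed_points_and_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        b = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        assert ssim(a, a) == pytest.approx(1.0)
        assert ssim(a, b) == pytest.approx(ssim(b, a))

    def test_matches_independent_windowed_reference(self):
        rng = np.random.default_rng(3)
        base = rng.normal(120, 30, (32, 32))
        noisy = base + rng.normal(0, 12, (32, 32))
        got = ssim(base, noisy, data_range=255.0)
        want = reference_ssim_windowed(base, noisy, 255.0)
        assert got == pytest.approx(want, abs=1e-7)

    def test_global_variant_matches_formula(self):
        rng = np.random.default_rng(5)
        a = rng.normal(100, 20, (16, 16))
        b = a + rng.normal(0, 10, (16, 16))
        got = ssim(a, b, data_range=255.0, windowed=False)
        mu_a, mu_b = a.mean(), b.mean()
        cov = ((a - mu_a) * (b - mu_b)).sum() / (a.size - 1)
        c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
        want = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)
                / ((mu_a**2 + mu_b**2 + c1)
                   * (a.var(ddof=1) + b.var(ddof=1) + c2)))
        assert got == pytest.approx(want, rel=1e-12)

    def test_color_images_average_channels(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 256, (3, 24, 24)).astype(np.uint8)
        per_chan = [ssim(a[c], a[c] // 2) for c in range(3)]
        assert ssim(a, a // 2) == pytest.approx(np.mean(per_chan))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ssim(np.zeros((4, 4)), np.zeros((5, 5)))


class TestPSNR:
    def test_worked_example(self):
        a = np.full((8, 8), 10.0)
        b = np.full((8, 8), 8.0)
        assert mse(a, b) == pytest.approx(4.0)
        assert psnr(a, b) == pytest.approx(10 * np.log10(100 / 4), abs=1e-10)
        assert psnr(a, b) == pytest.approx(13.9794, abs=1e-4)

    def test_identical_images_hit_infinity_sentinel(self):
        a = np.arange(16.0).reshape(4, 4)
        assert psnr(a, a.copy()) == float("inf")

    def test_mse_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(7, 9))
        b = rng.normal(size=(7, 9))
        acc = 0.0
        for i in range(7):
            for j in range(9):
                acc += (a[i, j] - b[i, j]) ** 2
        assert mse(a, b) == pytest.approx(acc / 63, rel=1e-12)

    def test_peak_uses_reference_maximum(self):
        a = np.full((4, 4), 50.0)
        b = a + 5.0
        assert psnr(a, b) == pytest.approx(10 * np.log10(50**2 / 25))


class TestLPIPS:
    def test_zero_for_identical_and_nonnegative(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(3, 8, 8))
        assert lpips(m, m.copy(), identity_extractor) == pytest.approx(0.0)
        m2 = rng.normal(size=(3, 8, 8))
        assert lpips(m, m2, identity_extractor) >= 0.0

    def test_identity_extractor_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(3, 8, 8))
        m0 = rng.normal(size=(3, 8, 8))
        na = m / np.sqrt((m**2).sum(axis=0, keepdims=True))
        nb = m0 / np.sqrt((m0**2).sum(axis=0, keepdims=True))
        want = ((na - nb) ** 2).sum(axis=0).mean()
        assert lpips(m, m0, identity_extractor) == pytest.approx(
            want, abs=1e-10)

    def test_missing_backend_is_explicit(self):
        with pytest.raises(ValueError, match="perceptual backend"):
            lpips(np.zeros((3, 4, 4)), np.zeros((3, 4, 4)))


class TestCV:
    def test_identical_stack_has_zero_cv(self):
        img = np.random.default_rng(0).integers(
            1, 255, (3, 8, 8)).astype(np.uint8)
        res = cv_analysis(np.stack([img] * 4))
        assert all(v == 0.0 for v in res.mean_cv.values())

    def test_two_uniform_images_worked_example(self):
        a = np.full((3, 4, 4), 90, np.uint8)
        b = np.full((3, 4, 4), 110, np.uint8)
        res = cv_analysis(np.stack([a, b]))
        # Y of a gray pixel equals its value; mean 100, sample SD sqrt(200)
        assert res.mean_cv["Y"] == pytest.approx(
            np.sqrt(200) / 100 * 100, rel=1e-9)

    def test_gaussian_jitter_recovers_sigma_over_mean(self):
        rng = np.random.default_rng(1)
        base = np.full((3, 64, 64), 100.0)
        stack = np.stack([
            np.clip(base + rng.normal(0, 2, base.shape), 0, 255)
            for _ in range(12)]).astype(np.uint8)
        res = cv_analysis(stack)
        # independent per-channel jitter mixes into Y with the BT.601
        # weights: SD_Y = sigma * ||(0.299, 0.587, 0.114)||
        want = 2.0 * np.linalg.norm([0.299, 0.587, 0.114])
        assert res.mean_cv["Y"] == pytest.approx(want, rel=0.10)

    def test_order_invariance_and_k_validation(self):
        rng = np.random.default_rng(2)
        stack = rng.integers(1, 255, (5, 3, 6, 6)).astype(np.uint8)
        a = cv_analysis(stack)
        b = cv_analysis(stack[::-1])
        assert a.mean_cv == b.mean_cv
        with pytest.raises(ValueError):
            cv_analysis(stack[:1])

    def test_bt601_coefficients_to_the_digit(self):
        rgb = np.zeros((3, 1, 1))
        rgb[0] = 255  # pure red
        y, cb, cr = rgb_to_ycbcr(rgb)[:, 0, 0]
        assert y == pytest.approx(0.299 * 255)
        assert cb == pytest.approx(128 - 0.168736 * 255)
        assert cr == pytest.approx(128 + 0.5 * 255)


class TestSpectrum:
    def test_constant_image_concentrates_at_dc(self):
        prof = radial_power_spectrum(np.full((32, 32), 3.0))
        assert prof[0] > 0
        np.testing.assert_allclose(prof[1:], 0, atol=1e-18)

    def test_pure_tone_peaks_at_its_frequency(self):
        x = np.arange(64)
        img = np.tile(np.sin(2 * np.pi * 8 * x / 64), (64, 1))
        prof = radial_power_spectrum(img)
        assert np.argmax(prof[1:]) + 1 == 8

    def test_parseval_consistency(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32))
        prof = radial_power_spectrum(img)
        n = 32
        yy, xx = np.ogrid[0:n, 0:n]
        r = np.rint(np.hypot(yy - n // 2, xx - n // 2)).astype(int)
        counts = np.bincount(r.ravel())
        total = (prof * counts).sum()
        want = (np.abs(np.fft.fft2(img)) ** 2).sum()
        assert total == pytest.approx(want, rel=1e-6)

    def test_binned_then_upsampled_image_is_band_limited(self):
        """N x N binning + bilinear upsampling strips energy above the
        folded band edge relative to the original."""
        rng = np.random.default_rng(3)
        img = gaussian_filter(rng.normal(size=(64, 64)), 0.8)
        N = 4
        low = img.reshape(16, N, 16, N).mean(axis=(1, 3))
        prof_full = radial_power_spectrum(img)
        prof_up = radial_power_spectrum(low, upsample_factor=N)
        cut = 64 // (2 * N)
        hi = slice(cut + 2, 32)
        assert prof_up[hi].sum() < prof_full[hi].sum()

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            radial_power_spectrum(np.zeros((8, 12)))


class TestPairedT:
    def test_textbook_example(self):
        b = np.zeros(3)
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t_test(a, b)
        assert res.t == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-12)
        assert res.t == pytest.approx(3.464, abs=1e-3)
        assert res.dof == 2 and not res.degenerate

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        assert paired_t_test(a, b).t == pytest.approx(
            -paired_t_test(b, a).t)
        assert paired_t_test(a, b).p == pytest.approx(paired_t_test(b, a).p)

    def test_identical_samples_flagged_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_t_test(a, a.copy())
        assert res.degenerate and np.isnan(res.t)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestExitPointSweep:
    def test_toy_variance_shrinks_with_larger_exit_point(self):
        """More noiseless steps (larger t_e) can only reduce the output
        spread of the mean strategy on the analytic toy."""
        from stainbridge.synthetic import generate_gaussian_toy
        toy = generate_gaussian_toy(T=200, dims=1, seed=6)
        rng = np.random.default_rng(0)
        _, yv = toy.sample_pairs(1, rng)
        y = yv[0]
        variances = [toy.sample_reverse(y, 2500, "mean", t_e=t_e,
                                        seed=4).var()
                     for t_e in (10, 60, 120, 200)]
        assert all(b <= a * 1.10 for a, b in zip(variances, variances[1:]))

    def test_grid_validation_and_reproducibility(self, micro_model,
                                                 holdout_pairs,
                                                 schedule_1000):
        from stainbridge.metrics import exit_point_sweep
        model, _ = micro_model
        with pytest.raises(ValueError):
            exit_point_sweep(model, schedule_1000, holdout_pairs, "mean",
                             [])
        with pytest.raises(ValueError):
            exit_point_sweep(model, schedule_1000, holdout_pairs, "mean",
                             [0, 10])

    def test_default_grid_matches_protocol(self):
        from stainbridge.metrics import DEFAULT_EXIT_POINTS
        assert len(DEFAULT_EXIT_POINTS) == 9
        assert DEFAULT_EXIT_POINTS[0] == 10
        assert DEFAULT_EXIT_POINTS[-1] == 500
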