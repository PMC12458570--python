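"""Clarity stack: edge energy, GMM blur score, FOV and focus detection."""

import numpy as np
import pytest
from scipy import ndimage

from lucid.clarity import (FovCircle, FovNotFoundError, assess_clarity, blur_score,
                           detect_focus_point, detect_fov, edge_energy,
                           final_blur_score, fit_edge_gmm, focus_score, fov_contrast,
                           GmmFit)
from lucid.frame_io import to_grayscale
from lucid.synthetic import SyntheticFrameSpec, generate_frame, random_frame_spec

BIG_FOV = FovCircle(center=(32.0, 32.0), radius=28.0, lightness_change=1.0)


class TestEdgeEnergy:
    def test_constant_image_all_zero(self):
        sample = edge_energy(np.full((64, 64), 0.5), BIG_FOV)
        assert not sample.values.any()
        assert sample.source_pixel_count > 0

    def test_step_edge_response_proportional_to_height(self):
        """Hand-convolving the Sobel kernel on a vertical step of height h
        gives a max response of 4h; doubling h doubles the response."""
        responses = []
        for h in (0.2, 0.4):
            img = np.zeros((64, 64))
            img[:, 32:] = h
            sample = edge_energy(img, BIG_FOV)
            responses.append(np.abs(sample.values).max())
            assert responses[-1] == pytest.approx(4 * h)
        assert responses[1] == pytest.approx(2 * responses[0])

    def test_blur_shrinks_the_tail(self):
        spec = SyntheticFrameSpec(blur_sigma=0.0, focus_offset=None, texture_seed=5)
        sharp = to_grayscale(generate_frame(spec).image)
        from dataclasses import replace

        blurred = to_grayscale(
            generate_frame(replace(spec, blur_sigma=4.0)).image
        )
        fov = FovCircle(center=spec.fov_center, radius=spec.fov_radius,
                        lightness_change=1.0)
        p99_sharp = np.percentile(np.abs(edge_energy(sharp, fov).values), 99)
        p99_blur = np.percentile(np.abs(edge_energy(blurred, fov).values), 99)
        assert p99_blur < p99_sharp

    def test_tiny_fov_rejected(self):
        tiny = FovCircle(center=(5.0, 5.0), radius=2.5, lightness_change=1.0)
        with pytest.raises(ValueError, match="kernel"):
            edge_energy(np.ones((10, 10)), tiny)


class TestGmm:
    def test_recovers_wide_component_sigma(self):
        rng = np.random.default_rng(0)
        draws = np.where(rng.uniform(size=10_000) < 0.5,
                         rng.normal(0, 0.01, 10_000), rng.normal(0, 0.2, 10_000))
        fit = fit_edge_gmm(type("S", (), {"values": draws})(), seed=0)
        assert fit.sigma_max == pytest.approx(0.2, rel=0.10)
        assert not fit.degenerate

    def test_single_gaussian_collapses_gracefully(self):
        rng = np.random.default_rng(1)
        draws = rng.normal(0, 0.1, 5_000)
        fit = fit_edge_gmm(type("S", (), {"values": draws})(), seed=0)
        assert fit.sigma_max == pytest.approx(0.1, rel=0.15)

    def test_all_identical_sample_degenerate(self):
        fit = fit_edge_gmm(type("S", (), {"values": np.zeros(100)})(), seed=0)
        assert fit.sigma_max == 0.0 and fit.degenerate

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_edge_gmm(type("S", (), {"values": np.ones(10)})())

    def test_weights_normalized(self):
        rng = np.random.default_rng(2)
        fit = fit_edge_gmm(type("S", (), {"values": rng.normal(0, 1, 500)})(), seed=0)
        assert sum(fit.weights) == pytest.approx(1.0, abs=1e-6)


class TestBlurScore:
    def _fit(self, sigma_max):
        return GmmFit((0, 0), (0.01, sigma_max), (0.5, 0.5), sigma_max)

    def test_zero_sigma_gives_zero(self):
        assert blur_score(self._fit(0.0), contrast=0.3) == 0.0

    def test_formula_value(self):
        assert blur_score(self._fit(0.2), 0.1, epsilon=1e-6) == pytest.approx(2.0, rel=1e-4)

    def test_inverse_in_contrast(self):
        a = blur_score(self._fit(0.2), 0.1)
        b = blur_score(self._fit(0.2), 0.2)
        assert a == pytest.approx(2 * b, rel=1e-4)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            blur_score(self._fit(0.1), contrast=-1.0)
        with pytest.raises(ValueError):
            blur_score(self._fit(0.1), contrast=0.1, epsilon=0.0)


class TestDetectFov:
    def test_recovers_synthetic_circle(self):
        spec = SyntheticFrameSpec(image_size=(400, 400), fov_center=(200.0, 200.0),
                                  fov_radius=100.0, eardrum_center=(200.0, 200.0),
                                  eardrum_radius=50.0, texture_seed=8)
        gray = to_grayscale(generate_frame(spec).image)
        fov = detect_fov(gray)
        assert abs(fov.center[0] - 200) <= 2 and abs(fov.center[1] - 200) <= 2
        assert abs(fov.radius - 100) <= 3

    def test_uniform_image_no_fov(self):
        with pytest.raises(FovNotFoundError):
            detect_fov(np.full((100, 100), 0.5))

    def test_true_rim_beats_inner_ring(self):
        """Two concentric candidate circles; only the outer has a lightness
        step, so lightness change selects it (brute-force delta-L agrees)."""
        h = w = 200
        yy, xx = np.mgrid[0:h, 0:w]
        d = np.hypot(xx - 100, yy - 100)
        gray = np.where(d <= 70, 0.8, 0.05)  # bright disk r=70
        # faint texture ring at r=50 creates an edge without a mean step
        ring = (np.abs(d - 50) < 1.5)
        gray = gray + 0.1 * ring * np.sign(np.sin(np.arctan2(yy - 100, xx - 100) * 20))
        fov = detect_fov(gray, radius_range=(40, 90), radius_step=1)
        assert fov.radius == pytest.approx(70, abs=3)

    def test_invariant_under_intensity_scaling(self):
        spec = SyntheticFrameSpec(texture_seed=9)
        gray = to_grayscale(generate_frame(spec).image)
        a = detect_fov(gray)
        b = detect_fov(0.3 * gray)
        assert a.center == b.center and a.radius == b.radius


class TestFocus:
    def test_flat_image_tie_breaks_to_origin(self):
        assert detect_focus_point(np.full((16, 16), 0.5)) == (0, 0)

    def test_sharp_patch_found_in_blurred_frame(self):
        spec = SyntheticFrameSpec(blur_sigma=6.0, focus_offset=(30.0, 0.0),
                                  texture_seed=12)
        gray = to_grayscale(generate_frame(spec).image)
        x, y = detect_focus_point(gray)
        assert np.hypot(x - 150, y - 120) <= 12

    def test_matches_brute_force_argmax(self, rng):
        """Exhaustive oracle: scan S(x, y) pixel by pixel on small inputs."""
        for _ in range(5):
            gray = rng.uniform(0, 1, size=(32, 32))
            smoothed = ndimage.gaussian_filter(gray, 2.0)
            sharpness = ndimage.laplace(smoothed) ** 2
            best, best_val = None, -1.0
            for row in range(32):
                for col in range(32):
                    if sharpness[row, col] > best_val:
                        best, best_val = (col, row), sharpness[row, col]
            assert detect_focus_point(gray, sigma_smooth=2.0) == best


class TestFocusScore:
    fov = FovCircle(center=(50.0, 50.0), radius=10.0, lightness_change=1.0)

    def test_center_focus_scores_radius(self):
        assert focus_score(self.fov, (50.0, 50.0)) == 10.0

    def test_rim_focus_scores_zero(self):
        assert focus_score(self.fov, (60.0, 50.0)) == 0.0

    def test_three_four_five(self):
        assert focus_score(self.fov, (53.0, 54.0)) == pytest.approx(5.0)

    def test_outside_fov_clamped_to_zero(self):
        assert focus_score(self.fov, (80.0, 80.0)) == 0.0

    def test_rotation_invariant_about_center(self, rng):
        for _ in range(20):
            rho, phi = rng.uniform(0, 15), rng.uniform(0, 2 * np.pi)
            p1 = (50 + rho * np.cos(phi), 50 + rho * np.sin(phi))
            p2 = (50 + rho, 50.0)
            assert focus_score(self.fov, p1) == pytest.approx(focus_score(self.fov, p2))


class TestFinalBlurScore:
    def test_zero_annihilates(self):
        assert final_blur_score(0.0, 7.0) == 0.0
        assert final_blur_score(3.0, 0.0) == 0.0

    def test_product(self):
        assert final_blur_score(2.0, 5.0) == 10.0

    def test_blur_lowers_composite_score(self):
        from dataclasses import replace

        spec = SyntheticFrameSpec(texture_seed=21)
        sharp = assess_clarity(to_grayscale(generate_frame(spec).image), seed=0)
        blurred = assess_clarity(
            to_grayscale(generate_frame(replace(spec, blur_sigma=4.0)).image), seed=0
        )
        assert sharp.s_blf > blurred.s_blf

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            final_blur_score(-1.0, 1.0)


class TestAssessClarity:
    def test_no_fov_frame_gets_zero_scores(self):
        result = assess_clarity(np.full((80, 80), 0.4), seed=0)
        assert result.fov is None and result.s_blf == 0.0

    def test_contrast_is_fov_restricted_std(self):
        gray = np.full((64, 64), 0.2)
        yy, xx = np.mgrid[0:64, 0:64]
        inside = (xx - 32) ** 2 + (yy - 32) ** 2 < (BIG_FOV.radius - 1) ** 2
        gray[inside] = np.linspace(0, 1, inside.sum())
        assert fov_contrast(gray, BIG_FOV) == pytest.approx(gray[inside].std())
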