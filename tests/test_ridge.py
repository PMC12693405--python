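"""Curvilinear (Steger-style) ridge detection and the ridge SD fraction."""

import numpy as np
import pytest

from podosem.io import CalibratedImage, PolygonRoi, rasterize_roi
from podosem.preprocess import BlurParams
from podosem.ridge import (LinePoint, RidgeLine, RidgeParams,
                           detect_line_points, detect_ridges, estimate_widths,
                           gaussian_derivatives, link_ridges,
                           matched_ridge_params, sd_fraction_by_ridge,
                           sd_mask_from_ridges, sweep_parameters)
from podosem.simulate import PatternSpec, make_pattern


def oblique_dark_line(theta_deg, offset=30.2, sigma_line=3.0, amp=0.5, size=96):
    """Dark line with Gaussian cross-profile at angle theta (normal form
    cosθ·x + sinθ·y = offset)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    th = np.deg2rad(theta_deg)
    d = np.cos(th) * xx + np.sin(th) * yy - offset
    return 1.0 - amp * np.exp(-(d**2) / (2 * sigma_line**2))


class TestDerivatives:
    def test_constant_image_all_zero(self):
        d = gaussian_derivatives(np.full((32, 32), 3.0), sigma=2.0)
        for k, v in d.items():
            np.testing.assert_allclose(v, 0.0, atol=1e-12)

    def test_linear_ramp(self):
        yy, xx = np.mgrid[0:64, 0:64].astype(float)
        d = gaussian_derivatives(xx, sigma=2.0)
        interior = (slice(12, 52), slice(12, 52))
        np.testing.assert_allclose(d["rx"][interior], 1.0, atol=1e-6)
        for k in ("ry", "rxx", "rxy", "ryy"):
            np.testing.assert_allclose(d[k][interior], 0.0, atol=1e-6)

    def test_bar_second_derivative_closed_form(self):
        """rxx at the center of a boxcar bar equals the analytic second
        derivative of the box⊛Gaussian profile."""
        from scipy.stats import norm
        size, a, sigma = 96, 6.0, 3.0   # bar half-width a
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        c = 47.5
        img = np.where(np.abs(xx - c) <= a, 0.0, 1.0)
        d = gaussian_derivatives(img, sigma=sigma)
        # smoothed profile f(x) = 1 - [Φ((x-c+a)/σ) - Φ((x-c-a)/σ)];
        # f''(center offset 0.5 px from c at pixel 48)
        x0 = 48.0 - c
        fpp = -(norm.pdf(x0 + a, scale=sigma) * (-(x0 + a) / sigma**2)
                - norm.pdf(x0 - a, scale=sigma) * (-(x0 - a) / sigma**2))
        assert abs(d["rxx"][48, 48] - fpp) < 1e-4

    def test_nonpositive_sigma(self):
        with pytest.raises(ValueError):
            gaussian_derivatives(np.zeros((8, 8)), sigma=0)


class TestLinePoints:
    def test_flat_image_empty(self):
        d = gaussian_derivatives(np.full((32, 32), 0.5), sigma=2.0)
        assert detect_line_points(d, RidgeParams(sigma=2.0)) == []

    @pytest.mark.parametrize("theta,tol", [(0.0, 0.10), (30.0, 0.15), (45.0, 0.15)])
    def test_subpixel_centerline_recovery(self, theta, tol):
        img = oblique_dark_line(theta)
        d = gaussian_derivatives(img, sigma=3.0)
        pts = detect_line_points(d, RidgeParams(sigma=3.0, lower_threshold=0.01),
                                 polarity="dark")
        th = np.deg2rad(theta)
        errs = [abs(np.cos(th) * p.position[0] + np.sin(th) * p.position[1] - 30.2)
                for p in pts
                if 15 < p.position[0] < 81 and 15 < p.position[1] < 81]
        assert len(errs) >= 20
        assert max(errs) < tol

    def test_polarity_selects_dark_vs_bright(self):
        img = oblique_dark_line(0.0)
        d = gaussian_derivatives(img, sigma=3.0)
        dark = detect_line_points(d, RidgeParams(sigma=3.0, lower_threshold=0.01),
                                  polarity="dark")
        bright = detect_line_points(d, RidgeParams(sigma=3.0, lower_threshold=0.01),
                                    polarity="bright")
        xs_dark = {round(p.position[0]) for p in dark}
        assert 30 in xs_dark
        assert not any(abs(p.position[0] - 30.2) < 1 for p in bright)


def _hand_point(x, y, saliency):
    return LinePoint(position=(float(x), float(y)), normal=(0.0, 1.0),
                     saliency=saliency, pixel=(int(round(y)), int(round(x))),
                     subpixel_offset=0.0)


class TestLinking:
    def test_gap_bridged_by_hysteresis(self):
        """Two collinear high-saliency runs separated by one low- (but
        above-lower-) saliency point link into a single line."""
        pts = ([_hand_point(x, 10, 0.5) for x in range(0, 5)]
               + [_hand_point(5, 10, 0.05)]
               + [_hand_point(x, 10, 0.5) for x in range(6, 11)])
        params = RidgeParams(sigma=2, lower_threshold=0.01, upper_threshold=0.2,
                             min_line_length=3)
        lines = link_ridges(pts, params)
        assert len(lines) == 1
        assert len(lines[0].points) == 11

    def test_short_line_discarded(self):
        pts = [_hand_point(x, 10, 0.5) for x in range(3)]  # length 2 px
        params = RidgeParams(sigma=2, lower_threshold=0.01, upper_threshold=0.2,
                             min_line_length=5)
        assert link_ridges(pts, params) == []

    def test_no_seed_below_upper_threshold(self):
        pts = [_hand_point(x, 10, 0.1) for x in range(20)]
        params = RidgeParams(sigma=2, lower_threshold=0.01, upper_threshold=0.2,
                             min_line_length=3)
        assert link_ridges(pts, params) == []

    def test_raising_upper_threshold_monotone_in_line_count(self, noisy_pattern,
                                                            matched_blur):
        _, image, _ = noisy_pattern
        from podosem.preprocess import gaussian_blur
        norm = gaussian_blur(image, matched_blur)
        norm = norm.with_pixels(norm.as_float())
        d = gaussian_derivatives(norm, sigma=4.0)
        counts = []
        for upper in (0.01, 0.02, 0.05, 0.1):
            params = RidgeParams(sigma=4.0, lower_threshold=0.01,
                                 upper_threshold=upper, min_line_length=5)
            pts = detect_line_points(d, params)
            counts.append(len(link_ridges(pts, params)))
        assert all(c2 <= c1 for c1, c2 in zip(counts, counts[1:]))


class TestWidths:
    def test_bar_width_recovered(self):
        """8-px boxcar bar, cap 15: mean estimated width within ±1.5 px."""
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        img = np.where(np.abs(xx - 47.5) <= 4.0, 0.3, 0.9)  # pixels 44..51 dark
        ci = CalibratedImage(img, scale=0.01)
        params = RidgeParams(sigma=8 / (2 * np.sqrt(3)), line_width=15,
                             lower_threshold=0.01, upper_threshold=0.05)
        lines = detect_ridges(ci, params)
        widths = np.concatenate([l.widths for l in lines])
        assert abs(np.mean(widths) - 8.0) < 1.5

    def test_wide_bar_capped(self):
        yy, xx = np.mgrid[0:96, 0:96].astype(float)
        img = np.where(np.abs(xx - 47.5) <= 12.0, 0.3, 0.9)  # 24 px bar
        ci = CalibratedImage(img, scale=0.01)
        params = RidgeParams(sigma=7.0, line_width=15, lower_threshold=0.005,
                             upper_threshold=0.02)
        lines = detect_ridges(ci, params)
        assert lines, "wide bar not detected"
        widths = np.concatenate([l.widths for l in lines])
        assert np.all(widths <= 15.0 + 1e-9)
        assert np.mean(widths) > 13.0  # cap fallback engaged

    def test_gaussian_ridge_width_matches_analytic_extrema(self):
        """For a pure Gaussian line profile the gradient extrema of the
        σ-smoothed profile sit at ±sqrt(σ_line² + σ_det²)."""
        sigma_line, sigma_det = 3.0, 2.0
        img = oblique_dark_line(0.0, sigma_line=sigma_line)
        ci = CalibratedImage(img, scale=0.01)
        params = RidgeParams(sigma=sigma_det, line_width=20,
                             lower_threshold=0.01, upper_threshold=0.05)
        lines = detect_ridges(ci, params)
        widths = np.concatenate([l.widths for l in lines])
        expected = 2 * np.sqrt(sigma_line**2 + sigma_det**2)
        assert abs(np.mean(widths) - expected) / expected < 0.10


class TestSdMask:
    def _straight_line(self, length=100, width=10.0, y=50.0):
        pts = [LinePoint(position=(x, y), normal=(0.0, 1.0), saliency=1.0,
                         pixel=(int(y), int(x)), subpixel_offset=0.0)
               for x in np.arange(10.0, 10.0 + length + 0.5, 1.0)]
        n = len(pts)
        return RidgeLine(points=pts, widths_left=np.full(n, width / 2),
                         widths_right=np.full(n, width / 2))

    def test_no_lines_empty_mask(self):
        roi = np.ones((50, 50), bool)
        assert sd_mask_from_ridges([], roi).sum() == 0

    def test_rectangle_area_oracle(self):
        roi = np.ones((120, 130), bool)
        mask = sd_mask_from_ridges([self._straight_line()], roi)
        assert abs(mask.sum() - 1000) / 1000 < 0.05

    def test_mask_subset_of_roi(self):
        roi = np.zeros((120, 130), bool)
        roi[40:60, 30:80] = True
        mask = sd_mask_from_ridges([self._straight_line()], roi)
        assert not (mask & ~roi).any()
        mask2 = sd_mask_from_ridges([self._straight_line()], roi,
                                    mode="inter-ridge", line_width=10)
        assert not (mask2 & ~roi).any()

    def test_jaccard_against_simulator_truth(self, noisy_pattern, default_roi_mask,
                                             matched_params, matched_blur):
        _, image, truth = noisy_pattern
        lines = detect_ridges(image, matched_params, blur=matched_blur)
        sd = sd_mask_from_ridges(lines, default_roi_mask)
        tr = truth.slit_mask & default_roi_mask
        jac = (sd & tr).sum() / (sd | tr).sum()
        assert jac >= 0.6


class TestSdFraction:
    def test_flat_image_zero(self):
        img = CalibratedImage(np.full((64, 64), 180, dtype=np.uint8), 0.01,
                              bit_depth=8)
        roi = PolygonRoi([(5, 5), (58, 5), (58, 58), (5, 58)])
        m = sd_fraction_by_ridge(img, roi)
        assert m.sd_fraction == 0.0

    def test_deterministic_bit_for_bit(self, noisy_pattern, default_roi,
                                       matched_params, matched_blur):
        _, image, _ = noisy_pattern
        m1 = sd_fraction_by_ridge(image, default_roi, blur=matched_blur,
                                  params=matched_params)
        m2 = sd_fraction_by_ridge(image, default_roi, blur=matched_blur,
                                  params=matched_params)
        assert m1.sd_fraction == m2.sd_fraction
        assert m1.sd_area == m2.sd_area

    def test_rotation_robustness(self, default_roi_mask, matched_params,
                                 matched_blur):
        roi = PolygonRoi([(60, 60), (195, 60), (195, 195), (60, 195)])

        def frac(img):
            return sd_fraction_by_ridge(img, roi, blur=matched_blur,
                                        params=matched_params).sd_fraction

        spec = PatternSpec(orientation=20.0, curvature=0.1, seed=5)
        img, _ = make_pattern(spec)
        f0 = frac(img)
        img90 = CalibratedImage(np.rot90(img.pixels).copy(), scale=img.scale,
                                bit_depth=8)
        assert abs(frac(img90) - f0) < 2.0
        img30, _ = make_pattern(PatternSpec(orientation=50.0, curvature=0.1, seed=5))
        assert abs(frac(img30) - f0) < 3.0

    def test_measured_fraction_monotone_in_truth(self, default_roi,
                                                 default_roi_mask,
                                                 matched_params, matched_blur):
        from scipy.stats import spearmanr
        truths, meas = [], []
        for frac in (20, 25, 30, 35, 40):
            spec = PatternSpec(slit_width=frac / 100 * 0.55, curvature=0.1,
                               orientation=17.0, seed=21)
            img, truth = make_pattern(spec, roi_mask=default_roi_mask)
            m = sd_fraction_by_ridge(img, default_roi, blur=matched_blur,
                                     params=matched_params)
            truths.append(truth.true_sd_fraction)
            meas.append(m.sd_fraction)
        rho = spearmanr(truths, meas).statistic
        assert rho >= 0.99


class TestSweep:
    def test_single_point_grid(self, noisy_pattern, default_roi_mask):
        _, image, truth = noisy_pattern
        table = sweep_parameters([(image, default_roi_mask, truth.slit_mask)],
                                 {"sigma": [4.0], "upper_threshold": [0.02],
                                  "lower_threshold": [0.01]},
                                 blur=BlurParams(radius=2.0))
        assert len(table) == 1
        assert 0 <= table.loc[0, "sensitivity"] <= 1

    def test_top_sigma_near_intrinsic_scale(self):
        """On a noiseless pattern the best-ranked sigma lies within a
        factor 1.5 of the groove's matched scale w/(2√3)."""
        spec = PatternSpec(curvature=0.0, noise_sd=0.0, orientation=15.0, seed=1)
        img, truth = make_pattern(spec)
        roi = np.ones((256, 256), bool)
        grid = {"sigma": [1.0, 1.5, 2.0, 3.0, 4.5, 6.0, 9.0, 13.0],
                "lower_threshold": [0.01], "upper_threshold": [0.02]}
        table = sweep_parameters([(img, roi, truth.slit_mask)], grid)
        intrinsic = (spec.slit_width / spec.scale) / (2 * np.sqrt(3))
        best = table.loc[0, "sigma"]
        assert intrinsic / 1.5 <= best <= intrinsic * 1.5

    def test_pure_noise_flagged(self):
        rng = np.random.default_rng(3)
        img = CalibratedImage((rng.uniform(0, 255, (64, 64))).astype(np.uint8),
                              0.01, bit_depth=8)
        roi = np.ones((64, 64), bool)
        truth = np.zeros((64, 64), bool)
        table = sweep_parameters([(img, roi, truth)], {"sigma": [3.0]})
        assert table.loc[0, "degenerate_cases"]
        assert np.isnan(table.loc[0, "sensitivity"])

    def test_empty_grid_rejected(self, noisy_pattern, default_roi_mask):
        _, image, truth = noisy_pattern
        with pytest.raises(ValueError):
            sweep_parameters([(image, default_roi_mask, truth.slit_mask)], {})
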