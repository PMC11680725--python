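"""Curve fitting, perpendicular profile sampling, sigmoid edges, rise distance."""

import numpy as np
import pytest

from selfgate import synth
from selfgate.sharpness import (
    RISE_FACTOR,
    SigmoidFit,
    fit_bezier,
    fit_sigmoid,
    image_sharpness,
    rise_distance,
    sample_perpendiculars,
)
from selfgate.synth import make_edge_phantom, sigmoid_edge


class TestBezier:
    def test_two_points_give_straight_segment(self):
        curve = fit_bezier([[0.0, 0.0], [10.0, 5.0]])
        t = np.linspace(0, 1, 33)
        pts = curve.point(t)
        expected = np.outer(t, [10.0, 5.0])
        np.testing.assert_allclose(pts, expected, atol=1e-12)

    def test_interpolates_all_control_points(self):
        rng = np.random.default_rng(0)
        pts = np.cumsum(rng.uniform(1, 3, (6, 2)), axis=0)
        curve = fit_bezier(pts)
        at_knots = curve.point(np.arange(6, dtype=float))
        np.testing.assert_allclose(at_knots, pts, atol=1e-10)

    def test_circle_radial_deviation_below_one_percent(self):
        # 8 samples per turn; walk 1.25 turns so the central full turn has
        # proper centred-difference tangents (endpoints are one-sided)
        ang = np.arange(12) * (2 * np.pi / 8)
        pts = np.stack([10 * np.cos(ang), 10 * np.sin(ang)], 1)
        curve = fit_bezier(pts)
        dense = curve.point(np.linspace(1.0, 9.0, 2000))  # interior segments
        r = np.hypot(dense[:, 0], dense[:, 1])
        assert np.max(np.abs(r - 10.0)) < 0.1

    def test_duplicate_points_raise(self):
        with pytest.raises(ValueError):
            fit_bezier([[0, 0], [0, 0], [1, 1]])


class TestPerpendiculars:
    def test_lines_perpendicular_to_straight_curve(self):
        img = np.zeros((64, 64))
        curve = fit_bezier([[10.0, 32.0], [54.0, 32.0]])
        _, tans = curve.sample_even(10)
        normals = np.stack([-tans[:, 1], tans[:, 0]], 1)
        dots = np.abs((tans * normals).sum(axis=1))
        assert np.max(dots) < 1e-12
        assert np.allclose(np.abs(normals[:, 1]), 1.0)  # vertical lines

    def test_even_arclength_spacing(self):
        curve = fit_bezier([[5.0, 30.0], [30.0, 34.0], [55.0, 30.0]])
        pts, _ = curve.sample_even(10)
        gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        # equal arc-length spacing; chord lengths agree for a gentle curve
        assert np.ptp(gaps) < 0.01 * gaps.mean()

    def test_noiseless_phantom_profiles_match_sigmoid(self):
        pts = [[10.0, 32.0], [54.0, 32.0]]  # horizontal interface
        img = make_edge_phantom(
            a0_px=0.0, a1=100, a2=10, s=0.5, image_size=64, curve_control_points=pts
        )
        curve = fit_bezier(pts)
        profiles = sample_perpendiculars(curve, 8, 8.0, img)
        assert len(profiles) == 8
        for coords, vals in profiles:
            expected = sigmoid_edge(coords, 0.0, 100, 10, 0.5)
            rms = np.sqrt(np.mean((vals - expected) ** 2))
            assert rms < 0.01 * (100 - 10)

    def test_line_exiting_image_dropped_with_warning(self):
        img = np.zeros((32, 32))
        curve = fit_bezier([[2.0, 2.0], [30.0, 2.0]])  # near the top edge
        with pytest.warns(UserWarning):
            profiles = sample_perpendiculars(curve, 5, 10.0, img)
        assert len(profiles) < 5


class TestFitSigmoid:
    def test_noiseless_self_fit_recovers_parameters(self):
        x = np.linspace(-15, 15, 61)
        y = sigmoid_edge(x, 0.0, 100.0, 10.0, 0.5)
        fit = fit_sigmoid(x, y)
        assert fit.converged
        np.testing.assert_allclose(
            [fit.a0, fit.a1, fit.a2, fit.s], [0.0, 100.0, 10.0, 0.5], atol=1e-6
        )

    def test_reversed_profile_negates_s_keeps_rd(self):
        x = np.linspace(-15, 15, 61)
        y = sigmoid_edge(x, 0.0, 100.0, 10.0, 0.5)
        fwd = fit_sigmoid(x, y)
        rev = fit_sigmoid(x, y[::-1])
        np.testing.assert_allclose(rev.s, -fwd.s, atol=1e-6)
        rd_f, _ = rise_distance(fwd, 220, 220)
        rd_r, _ = rise_distance(rev, 220, 220)
        np.testing.assert_allclose(rd_f, rd_r, atol=1e-9)

    def test_noisy_recovery_within_five_percent(self):
        x = np.linspace(-15, 15, 61)
        clean = sigmoid_edge(x, 0.0, 100.0, 10.0, 0.5)
        s_est = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            fit = fit_sigmoid(x, clean + rng.normal(0, 0.02 * 90, x.size))
            if fit.converged:
                s_est.append(fit.s)
        assert abs(np.mean(s_est) - 0.5) < 0.05 * 0.5

    def test_degenerate_profiles_raise(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(4), np.arange(4.0))
        with pytest.raises(ValueError):
            fit_sigmoid(np.arange(20), np.ones(20))


class TestRiseDistance:
    def test_closed_form_value_at_unit_steepness(self):
        fit = SigmoidFit(a0=0.0, a1=100.0, a2=10.0, s=1.0, residual=0.0, converged=True)
        rd, censored = rise_distance(fit, 220.0, 220)
        assert not censored
        np.testing.assert_allclose(rd, 2 * np.log10(9), atol=1e-9)  # ~1.9085 mm

    def test_doubling_s_halves_rd(self):
        f1 = SigmoidFit(0.0, 1.0, 0.0, 0.7, 0.0, True)
        f2 = SigmoidFit(0.0, 1.0, 0.0, 1.4, 0.0, True)
        rd1, _ = rise_distance(f1, 220.0, 220)
        rd2, _ = rise_distance(f2, 220.0, 220)
        np.testing.assert_allclose(rd1, 2 * rd2, rtol=1e-12)

    def test_invariant_to_intensity_affine_changes(self):
        rds = []
        for a1, a2 in [(100, 10), (1.0, 0.0), (5000, 4000)]:
            fit = SigmoidFit(3.0, float(a1), float(a2), 0.8, 0.0, True)
            rd, _ = rise_distance(fit, 220.0, 220)
            rds.append(rd)
        np.testing.assert_allclose(rds, rds[0], rtol=1e-12)

    def test_numerical_inverse_matches_closed_form(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            s = rng.uniform(0.05, 5.0) * rng.choice([-1, 1])
            fit = SigmoidFit(rng.uniform(-3, 3), 100.0, 10.0, s, 0.0, True)
            rd, _ = rise_distance(fit, 220.0, 220)
            np.testing.assert_allclose(rd, RISE_FACTOR / abs(s), rtol=1e-9)

    def test_vanishing_steepness_censored(self):
        fit = SigmoidFit(0.0, 100.0, 10.0, 1e-12, 0.0, True)
        rd, censored = rise_distance(fit, 220.0, 220, window_px=20)
        assert censored and rd == 20.0

    def test_nonconverged_fit_rejected(self):
        fit = SigmoidFit(0.0, 100.0, 10.0, 1.0, 0.0, False)
        with pytest.raises(ValueError):
            rise_distance(fit, 220.0, 220)


class TestImageSharpness:
    def test_phantom_loop_closure(self):
        """Sharpness pipeline on a noiseless generated edge recovers the
        generating steepness; pixel-aligned sampling keeps bilinear exact."""
        pts = [[10.0, 32.0], [54.0, 32.0]]
        img = make_edge_phantom(
            a0_px=0.0, a1=100, a2=10, s=0.5, image_size=64, curve_control_points=pts
        )
        curve = fit_bezier(pts)
        profiles = sample_perpendiculars(curve, 8, 8.0, img, step_px=1.0)
        for coords, vals in profiles:
            fit = fit_sigmoid(coords, vals)
            assert fit.converged
            assert abs(fit.s - 0.5) < 0.01 * 0.5

    def test_blur_monotonically_increases_rise_distance(self):
        from scipy.ndimage import gaussian_filter

        pts = [[10.0, 32.0], [54.0, 32.0]]
        img = make_edge_phantom(
            a0_px=0.0, a1=100, a2=10, s=2.0, image_size=64, curve_control_points=pts
        )
        medians = []
        for sigma in (0.0, 1.0, 2.0, 3.0):
            blurred = gaussian_filter(img, sigma) if sigma else img
            med, _, _ = image_sharpness(blurred, pts, 220.0, 220, n_lines=8, half_length_px=10)
            medians.append(med)
        assert np.all(np.diff(medians) > 0)
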