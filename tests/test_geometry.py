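"""Polynomial landmark registration: fitting, evaluation, warping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import musetransfer as mt
from musetransfer.geometry import polynomial_design_matrix

from conftest import pairs_from_transform, scattered_point_set

# Worked example: the twelve printed coefficients of a real sample's fit
EXAMPLE_A = [0.1681, 0.9862, 0.1141, 0.0281, -0.0755, -0.1059]
EXAMPLE_B = [0.1227, -0.0214, 0.9980, 0.0635, -0.1174, 0.0190]


def random_mild_transform(rng, direction=mt.MOVING_TO_FIXED, magnitude=0.05):
    a = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0]) + rng.uniform(-magnitude, magnitude, 6)
    b = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0]) + rng.uniform(-magnitude, magnitude, 6)
    return mt.PolynomialTransform2D(a=a, b=b, direction=direction)


class TestNormalization:
    def test_origin_and_corner_are_fixed_points(self):
        assert np.allclose(mt.normalize_points([(0, 0)], (123, 456)), [(0, 0)])
        assert np.allclose(mt.normalize_points([(456, 123)], (123, 456)), [(1, 1)])

    def test_division_by_width_and_height(self):
        out = mt.normalize_points([(37, 12)], (100, 200))
        assert np.allclose(out, [(0.185, 0.12)])
        back = mt.denormalize_points(out, (100, 200))
        assert np.allclose(back, [(37, 12)])

    def test_zero_sized_image_rejected(self):
        with pytest.raises(ValueError):
            mt.normalize_points([(1, 1)], (0, 10))

    @given(
        x=st.floats(0, 1e4, allow_nan=False),
        y=st.floats(0, 1e4, allow_nan=False),
        rows=st.integers(1, 10_000),
        cols=st.integers(1, 10_000),
    )
    @settings(deadline=None, derandomize=True)
    def test_round_trip_restores_pixels(self, x, y, rows, cols):
        pts = [(x, y)]
        back = mt.denormalize_points(mt.normalize_points(pts, (rows, cols)), (rows, cols))
        assert np.allclose(back, pts, rtol=1e-12, atol=1e-9)


class TestEvaluate:
    def test_identity_coefficients(self):
        t = mt.PolynomialTransform2D.identity()
        assert np.allclose(t([(0.3, 0.7)]), [(0.3, 0.7)])

    def test_printed_example_at_origin_returns_constant_terms(self):
        t = mt.PolynomialTransform2D(a=EXAMPLE_A, b=EXAMPLE_B, direction=mt.MOVING_TO_FIXED)
        out = t([(0.0, 0.0)])
        assert out[0, 0] == pytest.approx(0.1681, abs=0)
        assert out[0, 1] == pytest.approx(0.1227, abs=0)

    def test_printed_example_at_unit_corner_sums_coefficients(self):
        # sums computed by hand from the printed coefficients
        t = mt.PolynomialTransform2D(a=EXAMPLE_A, b=EXAMPLE_B, direction=mt.MOVING_TO_FIXED)
        out = t([(1.0, 1.0)])
        assert out[0, 0] == pytest.approx(1.1151, abs=1e-12)
        assert out[0, 1] == pytest.approx(1.0644, abs=1e-12)

    def test_non_finite_input_rejected(self):
        t = mt.PolynomialTransform2D.identity()
        with pytest.raises(ValueError):
            t([(np.nan, 0.0)])


class TestFit:
    def test_identity_mapping_recovers_identity_coefficients(self, rng):
        pts = scattered_point_set(rng, 6)
        cps = mt.ControlPointSet(pts, pts, (1000, 1000), (1000, 1000))
        t = mt.fit_transform(cps)
        assert np.allclose(t.a, [0, 1, 0, 0, 0, 0], atol=1e-10)
        assert np.allclose(t.b, [0, 0, 1, 0, 0, 0], atol=1e-10)

    def test_pure_translation_recovers_offset(self, rng):
        moving = scattered_point_set(rng, 8)
        fixed = moving + np.array([100.0, 200.0])  # 0.1 / 0.2 in normalized units
        cps = mt.ControlPointSet(fixed, moving, (1000, 1000), (1000, 1000))
        t = mt.fit_transform(cps)
        assert np.allclose(t.a, [0.1, 1, 0, 0, 0, 0], atol=1e-10)
        assert np.allclose(t.b, [0.2, 0, 1, 0, 0, 0], atol=1e-10)

    @pytest.mark.parametrize("n_pairs", [6, 12])
    def test_recovers_generating_coefficients(self, rng, n_pairs):
        for _ in range(5):
            truth = random_mild_transform(rng)
            cps = pairs_from_transform(truth, scattered_point_set(rng, n_pairs))
            fit = mt.fit_transform(cps)
            assert np.abs(fit.a - truth.a).max() <= 1e-8
            assert np.abs(fit.b - truth.b).max() <= 1e-8

    def test_six_pairs_interpolate_exactly(self, rng):
        truth = random_mild_transform(rng)
        cps = pairs_from_transform(truth, scattered_point_set(rng, 6))
        fit = mt.fit_transform(cps)
        assert fit.fit_report.per_point_px.max() <= 1e-9

    def test_consistent_extra_pair_leaves_fit_unchanged(self, rng):
        truth = random_mild_transform(rng)
        moving = scattered_point_set(rng, 8)
        fit8 = mt.fit_transform(pairs_from_transform(truth, moving))
        moving9 = np.vstack([moving, scattered_point_set(rng, 1)])
        fit9 = mt.fit_transform(pairs_from_transform(truth, moving9))
        assert np.abs(fit8.a - fit9.a).max() <= 1e-8
        assert np.abs(fit8.b - fit9.b).max() <= 1e-8

    def test_fewer_than_six_pairs_rejected(self, rng):
        pts = scattered_point_set(rng, 5)
        with pytest.raises(ValueError, match="6"):
            mt.ControlPointSet(pts, pts, (1000, 1000), (1000, 1000))

    def test_duplicates_deduplicated_before_count_check(self, rng):
        pts = scattered_point_set(rng, 6)
        stacked = np.vstack([pts[:3], pts[:3], pts[:3]])  # 9 rows, 3 distinct
        with pytest.raises(ValueError, match="6"):
            mt.ControlPointSet(stacked, stacked, (1000, 1000), (1000, 1000))

    def test_collinear_landmarks_raise_condition_error(self):
        x = np.linspace(100, 900, 8)
        pts = np.column_stack([x, 0.5 * x + 10.0])  # all on one line
        cps = mt.ControlPointSet(pts, pts, (1000, 1000), (1000, 1000))
        with pytest.raises(mt.DegenerateLandmarksError, match="cond"):
            mt.fit_transform(cps)

    def test_matches_independent_polynomial_estimator(self, rng):
        # cross-check against skimage's degree-2 polynomial estimator on the
        # same normalized correspondences
        from skimage.transform import estimate_transform

        truth = random_mild_transform(rng)
        moving = scattered_point_set(rng, 10)
        cps = pairs_from_transform(truth, moving)
        fit = mt.fit_transform(cps)
        src = mt.normalize_points(cps.moving, cps.moving_shape)
        dst = mt.normalize_points(cps.fixed, cps.fixed_shape)
        ref = estimate_transform("polynomial", src, dst, order=2)
        # skimage orders the basis as [1, x, y, x^2, xy, y^2] too
        assert np.allclose(fit.a, ref.params[0], atol=1e-8)
        assert np.allclose(fit.b, ref.params[1], atol=1e-8)


class TestInverse:
    def test_identity_points_give_identity_both_ways(self, rng):
        pts = scattered_point_set(rng, 8)
        cps = mt.ControlPointSet(pts, pts, (1000, 1000), (1000, 1000))
        for t in (mt.fit_transform(cps), mt.fit_inverse_transform(cps)):
            assert np.allclose(t.a, [0, 1, 0, 0, 0, 0], atol=1e-10)
            assert np.allclose(t.b, [0, 0, 1, 0, 0, 0], atol=1e-10)

    def test_translation_points_give_negated_offsets(self, rng):
        moving = scattered_point_set(rng, 8)
        fixed = moving + np.array([100.0, 200.0])
        cps = mt.ControlPointSet(fixed, moving, (1000, 1000), (1000, 1000))
        inv = mt.fit_inverse_transform(cps)
        assert inv.direction == mt.FIXED_TO_MOVING
        assert np.allclose(inv.a, [-0.1, 1, 0, 0, 0, 0], atol=1e-10)
        assert np.allclose(inv.b, [-0.2, 0, 1, 0, 0, 0], atol=1e-10)

    def test_forward_then_inverse_round_trip_below_half_pixel(self, rng):
        shape = (1000, 1000)
        for _ in range(5):
            truth = random_mild_transform(rng)
            cps = pairs_from_transform(truth, scattered_point_set(rng, 12), shape)
            fwd, inv = mt.fit_transform(cps), mt.fit_inverse_transform(cps)
            m = cps.moving
            f = mt.denormalize_points(fwd(mt.normalize_points(m, shape)), shape)
            back = mt.denormalize_points(inv(mt.normalize_points(f, shape)), shape)
            rms = np.sqrt(np.mean(np.sum((back - m) ** 2, axis=1)))
            assert rms < 0.5


class TestWarp:
    def test_identity_transform_reproduces_image(self, rng):
        img = rng.random((40, 50))
        out = mt.warp_image(img, mt.PolynomialTransform2D.identity(), (40, 50))
        assert np.allclose(out, img)

    def test_integer_translation_matches_index_shift_oracle(self, rng):
        img = rng.random((40, 40))
        dx, dy = 5, -3  # output (x,y) samples input at (x+dx, y+dy)
        t = mt.PolynomialTransform2D(
            a=[dx / 40, 1, 0, 0, 0, 0], b=[dy / 40, 0, 1, 0, 0, 0],
            direction=mt.MOVING_TO_FIXED,
        )
        out = mt.warp_image(img, t, (40, 40), interpolation="nearest")
        oracle = np.zeros_like(img)
        oracle[3:, : 40 - 5] = img[: 40 - 3, 5:]
        assert np.allclose(out, oracle)

    def test_nearest_keeps_masks_binary(self, rng):
        mask = (rng.random((60, 60)) > 0.5).astype(np.uint8)
        t = random_mild_transform(rng)
        out = mt.warp_image(mask, t, (60, 60), interpolation="nearest")
        assert set(np.unique(out)) <= {0, 1}

    def test_direction_mismatch_raises(self, rng):
        img = rng.random((20, 20))
        t = mt.PolynomialTransform2D.identity(direction=mt.MOVING_TO_FIXED)
        with pytest.raises(ValueError, match="direction"):
            mt.warp_image(img, t, (20, 20), expected_direction=mt.FIXED_TO_MOVING)

    def test_out_of_bounds_filled_with_constant(self):
        img = np.ones((10, 10))
        t = mt.PolynomialTransform2D(
            a=[2.0, 1, 0, 0, 0, 0], b=[0, 0, 1, 0, 0, 0], direction=mt.MOVING_TO_FIXED
        )
        out = mt.warp_image(img, t, (10, 10), fill=0.0)
        assert np.all(out == 0.0)


class TestRegistrationQuality:
    def test_identical_and_disjoint_masks(self):
        a = np.zeros((10, 10), dtype=bool)
        a[2:5, 2:5] = True
        b = np.zeros_like(a)
        b[6:9, 6:9] = True
        assert mt.registration_quality(a, a) == 1.0
        assert mt.registration_quality(a, b) == 0.0

    def test_exact_points_beat_jittered_points(self):
        # averaged over seeds, jittering the landmarks cannot improve the
        # tissue-overlap quality score
        exact, jittered = [], []
        for seed in range(10):
            s = mt.generate_phantom(seed=seed, shape=(600, 600))
            for sigma, acc in ((0.0, exact), (5.0, jittered)):
                cps = (
                    mt.perturb_control_points(s.control_points, sigma, seed=seed)
                    if sigma
                    else s.control_points
                )
                inv = mt.fit_inverse_transform(cps)
                warped = mt.warp_image(
                    s.true_tissue_mask_raw.astype(np.uint8),
                    inv,
                    (600, 600),
                    interpolation="nearest",
                ).astype(bool)
                acc.append(mt.registration_quality(warped, s.true_tissue_mask))
        assert np.mean(exact) >= np.mean(jittered)


def test_design_matrix_basis_order():
    d = polynomial_design_matrix([(2.0, 3.0)])
    assert np.allclose(d, [[1, 2, 3, 4, 6, 9]])


def test_transform_json_round_trip(tmp_path, rng):
    t = random_mild_transform(rng)
    t.input_shape = (600, 700)
    t.output_shape = (800, 900)
    path = tmp_path / "t.json"
    t.to_json(path)
    back = mt.PolynomialTransform2D.from_json(path)
    assert np.array_equal(back.a, t.a) and np.array_equal(back.b, t.b)
    assert back.direction == t.direction
    assert back.input_shape == t.input_shape and back.output_shape == t.output_shape
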