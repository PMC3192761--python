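import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import histo3d as h
from histo3d.alignment import DegenerateLandmarksError, RigidTransform2D

from .oracles import grid_search_rigid

# landmark spread comparable to clicking corners of a full camera frame
POINTS = np.array([[100.0, 100.0], [500.0, 120.0], [300.0, 400.0], [120.0, 330.0]])


class TestEstimateRigid:
    def test_identical_points_give_identity_with_zero_residual(self):
        t, rms = h.estimate_rigid_from_landmarks(h.LandmarkPairs(POINTS, POINTS))
        assert t.theta == pytest.approx(0.0, abs=1e-12)
        assert (t.tx, t.ty) == pytest.approx((0.0, 0.0), abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_pure_translation_recovered_exactly(self):
        t, rms = h.estimate_rigid_from_landmarks(
            h.LandmarkPairs(fixed=POINTS + [5.0, -3.0], moving=POINTS)
        )
        assert t.theta == pytest.approx(0.0, abs=1e-12)
        assert (t.tx, t.ty) == pytest.approx((5.0, -3.0), abs=1e-9)
        assert rms == pytest.approx(0.0, abs=1e-9)

    def test_noisy_rotation_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        centroid = POINTS.mean(axis=0)
        true = RigidTransform2D.about_center(
            math.radians(10.0), (4.0, -2.0), tuple(centroid)
        )
        fixed = true.apply(POINTS) + rng.normal(0, 0.5, POINTS.shape)
        est, rms = h.estimate_rigid_from_landmarks(h.LandmarkPairs(fixed, POINTS))
        assert abs(math.degrees(est.theta) - 10.0) < 0.5
        # exhaustive grid search (rotation about the landmark centroid) must
        # agree with the closed-form fit to within the grid resolution
        ora_theta, ora_tx, ora_ty = grid_search_rigid(
            fixed, POINTS, theta_range=math.radians(15), t_range=8.0
        )
        _, est_tx, est_ty = est.params_about_center(tuple(POINTS.mean(axis=0)))
        assert abs(ora_theta - est.theta) <= math.radians(30) / 80 + 1e-9
        assert abs(ora_tx - est_tx) <= 16.0 / 40 + 1e-9
        assert abs(ora_ty - est_ty) <= 16.0 / 40 + 1e-9
        assert rms < 1.0

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        theta=st.floats(-math.pi, math.pi),
        tx=st.floats(-50, 50),
        ty=st.floats(-50, 50),
    )
    def test_estimate_recovers_any_applied_transform_exactly(self, theta, tx, ty):
        true = RigidTransform2D(theta, tx, ty)
        est, rms = h.estimate_rigid_from_landmarks(
            h.LandmarkPairs(fixed=true.apply(POINTS), moving=POINTS)
        )
        np.testing.assert_allclose(est.matrix, true.matrix, atol=1e-8)
        assert rms < 1e-7

    def test_too_few_or_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateLandmarksError):
            h.LandmarkPairs(POINTS[:1], POINTS[:1])
        same = np.tile([[5.0, 5.0]], (4, 1))
        with pytest.raises(DegenerateLandmarksError):
            h.estimate_rigid_from_landmarks(h.LandmarkPairs(POINTS, same))

    def test_phantom_misalignment_recovered_below_one_pixel(self, clean_sections):
        """Injected per-section misalignment (sigma 5 px / 2 deg) is recovered
        to well under 1 px / 0.5 deg from ground-truth landmarks."""
        sections, _ = clean_sections
        _, corrections = h.perturb_alignment(sections, 5.0, 2.0, seed=11)
        grid = np.array(
            [[x, y] for x in (15.0, 60.0, 105.0) for y in (15.0, 60.0, 105.0)]
        )
        t_errs, a_errs = [], []
        for corr in corrections:
            displace = corr.inverse()
            est, _ = h.estimate_rigid_from_landmarks(
                h.LandmarkPairs(fixed=grid, moving=displace.apply(grid))
            )
            a_errs.append(abs(math.degrees(est.theta - corr.theta)))
            t_errs.append(math.hypot(est.tx - corr.tx, est.ty - corr.ty))
        assert np.mean(t_errs) < 1.0
        assert np.mean(a_errs) < 0.5


class TestCompose:
    def test_identity_chain(self):
        absolute = h.compose_to_reference([RigidTransform2D.identity()] * 5)
        assert all(t.is_identity(tol=1e-12) for t in absolute)

    def test_translations_accumulate(self):
        absolute = h.compose_to_reference([RigidTransform2D(0, 1, 0)] * 5)
        assert (absolute[5].tx, absolute[5].ty) == pytest.approx((5.0, 0.0))

    def test_matches_sequential_matrix_products(self, rng):
        pairwise = [
            RigidTransform2D(rng.uniform(-1, 1), rng.uniform(-5, 5), rng.uniform(-5, 5))
            for _ in range(6)
        ]
        absolute = h.compose_to_reference(pairwise)
        m = np.eye(3)
        for i, t in enumerate(pairwise):
            m = m @ t.matrix
            np.testing.assert_allclose(absolute[i + 1].matrix, m, atol=1e-10)

    def test_inverse_composes_to_identity(self):
        t = RigidTransform2D(0.3, 4.0, -2.0)
        np.testing.assert_allclose(t.compose(t.inverse()).matrix, np.eye(3), atol=1e-12)


class TestResample:
    def test_identity_is_bit_exact(self, random_section):
        out = h.resample_section(random_section, RigidTransform2D.identity(), "nearest")
        np.testing.assert_array_equal(out.pixels, random_section.pixels)

    def test_integer_translation_is_exact_shift_with_white_fill(self, random_section):
        out = h.resample_section(random_section, RigidTransform2D(0, 3, -2), "nearest")
        src = random_section.pixels
        np.testing.assert_array_equal(out.pixels[:-2, 3:], src[2:, :-3])
        assert (out.pixels[:, :3] == 255).all()  # vacated left edge
        assert (out.pixels[-2:, :] == 255).all()  # vacated bottom edge

    def test_quarter_turn_matches_index_permutation(self, rng):
        img = rng.integers(0, 256, size=(31, 31, 3)).astype(np.uint8)
        sec = h.SectionImage(img, 1.0, 0, 5.0)
        center = ((31 - 1) / 2.0, (31 - 1) / 2.0)
        t = RigidTransform2D.about_center(math.pi / 2, (0.0, 0.0), center)
        out = h.resample_section(sec, t, "nearest")
        # hand-derived index remap: out[y, x] = img[H-1-x, y] for a square image
        np.testing.assert_array_equal(out.pixels, np.rot90(img, 3, axes=(0, 1)))

    def test_round_trip_restores_interior(self, random_section):
        t = RigidTransform2D(0, 4.3, -2.7)
        fwd = h.resample_section(random_section, t, "nearest")
        back = h.resample_section(fwd, t.inverse(), "nearest")
        np.testing.assert_array_equal(
            back.pixels[8:-8, 8:-8], random_section.pixels[8:-8, 8:-8]
        )

    def test_unknown_interpolation_rejected(self, random_section):
        with pytest.raises(ValueError):
            h.resample_section(random_section, RigidTransform2D.identity(), "cubic")


class TestAutoAlign:
    def test_self_alignment_is_identity(self, clean_sections):
        sec = clean_sections[0][6]
        t = h.auto_align_pair(sec, sec)
        assert math.hypot(t.tx, t.ty) < 1.0
        assert abs(math.degrees(t.theta)) < 0.26

    def test_known_shift_recovered(self, clean_sections):
        sec = clean_sections[0][6]
        moved = h.resample_section(sec, RigidTransform2D(0, 7, -4), "nearest")
        t = h.auto_align_pair(moved, sec)
        assert abs(t.tx - 7) <= 1.0 and abs(t.ty + 4) <= 1.0

    def test_injected_rotation_and_shift_recovered(self, clean_sections):
        sec = clean_sections[0][6]
        h_, w_ = sec.shape
        center = ((w_ - 1) / 2.0, (h_ - 1) / 2.0)
        true = RigidTransform2D.about_center(math.radians(3.0), (5.0, 2.0), center)
        moved = h.resample_section(sec, true)
        est = h.auto_align_pair(moved, sec)
        assert abs(math.degrees(est.theta - true.theta)) <= 1.0
        est_c = est.params_about_center(center)
        true_c = true.params_about_center(center)
        assert math.hypot(est_c[1] - true_c[1], est_c[2] - true_c[2]) <= 2.0

    def test_featureless_image_rejected(self):
        blank = h.SectionImage(np.full((32, 32, 3), 200, np.uint8), 1.0, 0, 5.0)
        from histo3d.alignment import AlignmentFailureError

        with pytest.raises(AlignmentFailureError):
            h.auto_align_pair(blank, blank)
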