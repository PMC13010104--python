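"""Shape descriptors: ellipse fitting, curvature, lengths, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from trunksim.kinematics import (ClassThresholds, EllipseSection,
                                 KinematicsError, MovementClass,
                                 classify_movement, fit_section_ellipse,
                                 relative_bend_angles, segment_curvature,
                                 segment_length, shape_timeseries)
from trunksim.synthetic_data import GeneratorSpec, generate_reaching_trial


def ellipse_points(center, R, a, b, phis):
    return (np.asarray(center)[None, :]
            + np.outer(a * np.cos(phis), R[:, 0])
            + np.outer(b * np.sin(phis), R[:, 1]))


class TestFitSectionEllipse:
    def test_recovers_known_tilted_ellipse(self):
        R = Rotation.from_euler("ZYX", [0.4, -0.7, 0.25]).as_matrix()
        center = np.array([0.3, -0.1, 1.2])
        phis = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        pts = ellipse_points(center, R, 0.08, 0.05, phis)
        sec = fit_section_ellipse(pts, row_index=1)
        assert np.allclose(sec.center, center, atol=1e-6)
        assert sec.semi_axes[0] == pytest.approx(0.08, abs=1e-6)
        assert sec.semi_axes[1] == pytest.approx(0.05, abs=1e-6)
        # plane normal and major axis recovered up to sign
        Rf = sec.rotation
        assert abs(Rf[:, 2] @ R[:, 2]) == pytest.approx(1.0, abs=1e-6)
        assert abs(Rf[:, 0] @ R[:, 0]) == pytest.approx(1.0, abs=1e-6)
        assert sec.fit_rms == pytest.approx(0.0, abs=1e-7)

    def test_circle_in_xy_plane(self):
        phis = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pts = np.column_stack([0.05 * np.cos(phis), 0.05 * np.sin(phis),
                               np.zeros(6)])
        sec = fit_section_ellipse(pts)
        assert np.allclose(sec.center, 0.0, atol=1e-9)
        assert sec.semi_axes[0] == pytest.approx(0.05, abs=1e-6)
        assert sec.semi_axes[1] == pytest.approx(0.05, abs=1e-6)

    def test_too_few_points_error(self):
        pts = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(KinematicsError, match="row 3"):
            fit_section_ellipse(pts, row_index=3)

    def test_collinear_points_error(self):
        pts = np.outer(np.linspace(0, 1, 6), [1.0, 2.0, 0.5])
        with pytest.raises(KinematicsError, match="collinear"):
            fit_section_ellipse(pts)

    def test_partial_arc_warns(self):
        phis = np.linspace(-np.pi / 3, np.pi / 3, 8)  # 120 degrees
        pts = ellipse_points([0, 0, 0], np.eye(3), 0.08, 0.05, phis)
        with pytest.warns(UserWarning, match="cover"):
            fit_section_ellipse(pts)


class TestSegmentLength:
    def test_examples(self):
        assert segment_length([0, 0, 0], [0.2, 0, 0]) == pytest.approx(0.2)
        assert segment_length([1, 2, 2], [2, 4, 4]) == pytest.approx(3.0)
        assert segment_length([1, 1, 1], [1, 1, 1]) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=9, max_size=9))
    def test_symmetry_and_triangle_inequality(self, coords):
        a, b, c = np.array(coords).reshape(3, 3)
        assert segment_length(a, b) == segment_length(b, a)
        assert segment_length(a, c) <= (segment_length(a, b)
                                        + segment_length(b, c) + 1e-12)


class TestRelativeBendAngles:
    @staticmethod
    def _sec(R, row=1):
        return EllipseSection.from_rotation(row, np.zeros(3), R, (0.1, 0.08))

    def test_identity_gives_zero(self):
        R = Rotation.from_euler("ZYX", [0.2, 0.1, -0.3]).as_matrix()
        assert relative_bend_angles(self._sec(R), self._sec(R, 2)) == (0.0, 0.0)

    def test_pure_rotation_about_minor_axis(self):
        R1 = np.eye(3)
        R2 = R1 @ Rotation.from_rotvec([0, np.radians(4.0), 0]).as_matrix()
        alpha, beta = relative_bend_angles(self._sec(R1), self._sec(R2, 2))
        assert alpha == pytest.approx(4.0, abs=1e-9)
        assert beta == pytest.approx(0.0, abs=1e-9)

    def test_matches_quaternion_oracle(self):
        """Axis-angle components agree with an independent quaternion log map."""
        rng = np.random.default_rng(11)
        for _ in range(25):
            R1 = Rotation.random(rng=rng).as_matrix()
            small = Rotation.from_rotvec(rng.normal(0, 0.05, 3))
            R2 = R1 @ small.as_matrix()
            alpha, beta = relative_bend_angles(self._sec(R1), self._sec(R2, 2))
            # oracle: quaternion of the relative rotation, log map by hand
            q = small.as_quat()  # (x, y, z, w)
            v, w = q[:3], q[3]
            ang = 2.0 * np.arctan2(np.linalg.norm(v), w)
            axis = v / np.linalg.norm(v)
            rotvec_deg = np.degrees(ang) * axis
            assert alpha == pytest.approx(rotvec_deg[1], abs=1e-8)
            assert beta == pytest.approx(rotvec_deg[0], abs=1e-8)


class TestSegmentCurvature:
    def test_three_four_five(self):
        sh = segment_curvature(4.0, 3.0, 0.2)
        assert sh.K_alpha == pytest.approx(20.0)
        assert sh.K_beta == pytest.approx(15.0)
        assert sh.K == pytest.approx(25.0)

    def test_zero_angles(self):
        assert segment_curvature(0.0, 0.0, 0.3).K == 0.0

    def test_zero_length_errors(self):
        with pytest.raises(KinematicsError):
            segment_curvature(1.0, 1.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-90, 90), st.floats(-90, 90),
           st.floats(0.01, 1.0))
    def test_norm_identity(self, alpha, beta, L):
        sh = segment_curvature(alpha, beta, L)
        assert sh.K == pytest.approx(np.hypot(sh.K_alpha, sh.K_beta), rel=1e-9)


class TestShapeTimeseries:
    def test_recovers_commanded_curvature(self):
        trial, truth = generate_reaching_trial(
            GeneratorSpec(peak_K=25.0, duration=1.0, sample_rate=25, seed=4))
        shapes = shape_timeseries(trial)
        peak = shapes.K[4, -1]
        assert peak == pytest.approx(truth.K[4, -1], rel=0.02)

    def test_straight_rest_trial(self):
        trial, truth = generate_reaching_trial(
            GeneratorSpec(peak_K=0.0, duration=0.2, sample_rate=50, seed=0))
        shapes = shape_timeseries(trial)
        assert np.allclose(shapes.K, 0.0, atol=1e-9)
        assert np.allclose(shapes.L, truth.L, atol=1e-12)

    def test_single_sample_trial(self):
        trial, _ = generate_reaching_trial(
            GeneratorSpec(peak_K=10.0, duration=0.02, sample_rate=50, seed=0))
        one = trial.sections[:1]
        from trunksim.kinematics import MovementTrial

        single = MovementTrial(sections=one, sample_rate=50.0)
        shapes = shape_timeseries(single)
        assert shapes.K.shape == (9, 1)

    def test_frame_invariance_under_rigid_transform(self):
        """A global rotation+translation leaves every shape descriptor unchanged."""
        trial, _ = generate_reaching_trial(
            GeneratorSpec(movement_class="BE", peak_K=30.0,
                          elongation_fraction=0.1, duration=0.5,
                          sample_rate=20, seed=5))
        ref = shape_timeseries(trial)
        Rg = Rotation.from_euler("ZYX", [0.7, -0.4, 0.2])
        shift = np.array([1.0, -2.0, 0.5])
        moved = [
            [EllipseSection.from_rotation(
                sec.row_index, Rg.apply(sec.center) + shift,
                Rg.as_matrix() @ sec.rotation, sec.semi_axes, sec.timestamp)
             for sec in sample]
            for sample in trial.sections
        ]
        from trunksim.kinematics import MovementTrial

        shapes = shape_timeseries(MovementTrial(sections=moved,
                                                sample_rate=trial.sample_rate))
        assert np.allclose(shapes.K, ref.K, atol=1e-9)
        assert np.allclose(shapes.L, ref.L, atol=1e-9)


class TestClassification:
    @staticmethod
    def _shapes(Kmax, dLmax, L0=0.2):
        from trunksim.kinematics import ShapeSeries

        n_seg, n_t = 9, 10
        K = np.zeros((n_seg, n_t))
        L = np.full((n_seg, n_t), L0)
        K[3, 5] = Kmax
        L[3, 5] = L0 + dLmax
        z = np.zeros_like(K)
        return ShapeSeries(times=np.arange(n_t) / 10, K=K, K_alpha=K,
                           K_beta=z, alpha=K * L, beta=z, L=L)

    def test_bending(self):
        assert classify_movement(self._shapes(25.0, 0.005)) is MovementClass.B

    def test_bending_elongation(self):
        assert classify_movement(self._shapes(25.0, 0.03)) is MovementClass.BE

    def test_below_threshold_is_other(self):
        assert classify_movement(self._shapes(10.0, 0.03)) is MovementClass.OTHER

    def test_threshold_monotonicity(self):
        """Raising K_thresh never converts OTHER into B/BE."""
        shapes = self._shapes(25.0, 0.005)
        lo = classify_movement(shapes, ClassThresholds(20.0, 0.02))
        hi = classify_movement(shapes, ClassThresholds(30.0, 0.02))
        assert lo is MovementClass.B
        assert hi is MovementClass.OTHER

    def test_thresholds_validated(self):
        with pytest.raises(KinematicsError):
            ClassThresholds(-1.0, 0.02)
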