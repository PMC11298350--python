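"""Rigid-transform algebra, SVD registration and joint-frame motion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivjoint.errors import DegenerateGeometryError, InputError
from ivjoint.frames import JointPose
from ivjoint.kinematics import (
    PointSet,
    RigidTransform,
    estimate_rigid_transform,
    euler_compose,
    euler_decompose,
    motion_about_joint,
    rotation_matrix,
    rotation_vector,
)


def random_rotation(rng):
    return rotation_matrix(rng.normal(size=3) * rng.uniform(0, np.pi * 0.9))


def random_transform(rng):
    return RigidTransform(random_rotation(rng), rng.normal(size=3) * 0.01)


class TestRigidTransform:
    def test_identity_and_inverse_roundtrip(self, rng):
        for _ in range(50):
            t = random_transform(rng)
            eye = t.compose(t.inverse())
            assert np.abs(eye.rotation - np.eye(3)).max() < 1e-12
            assert np.abs(eye.translation).max() < 1e-12

    def test_compose_matches_homogeneous_matrix_product(self, rng):
        """4x4 homogeneous-matrix multiplication is the independent oracle."""
        for _ in range(50):
            a, b = random_transform(rng), random_transform(rng)
            ab = a.compose(b)
            ref = a.matrix() @ b.matrix()
            assert np.abs(ab.matrix() - ref).max() < 1e-12
            ba = b.compose(a)
            assert np.abs(ba.matrix() - b.matrix() @ a.matrix()).max() < 1e-12
            # composition is order-sensitive for generic transforms
            assert np.abs(ab.matrix() - ba.matrix()).max() > 1e-8

    def test_apply_identity_preserves_pointset(self, rng):
        ps = PointSet(["a", "b", "c"], rng.normal(size=(3, 3)))
        out = RigidTransform.identity().apply_to_pointset(ps)
        np.testing.assert_array_equal(out.coords, ps.coords)
        assert out.labels == ps.labels

    def test_non_orthonormal_rotation_rejected(self):
        with pytest.raises(InputError):
            RigidTransform(np.eye(3) * 1.001, np.zeros(3))
        with pytest.raises(InputError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))

    def test_json_roundtrip(self, rng):
        t = random_transform(rng)
        t2 = RigidTransform.from_dict(t.to_dict())
        assert np.abs(t2.rotation - t.rotation).max() < 1e-15
        assert np.abs(t2.translation - t.translation).max() < 1e-15


class TestEstimateRigidTransform:
    def test_identical_sets_give_identity(self, rng):
        ps = PointSet([f"p{i}" for i in range(5)], rng.normal(size=(5, 3)))
        t, rms = estimate_rigid_transform(ps, ps)
        assert np.abs(t.rotation - np.eye(3)).max() < 1e-12
        assert np.abs(t.translation).max() < 1e-12
        assert rms < 1e-12

    def test_noiseless_recovery_is_exact(self, rng):
        """90 deg about Z plus (1, 2, 3) mm shift is recovered exactly."""
        src = PointSet([f"p{i}" for i in range(6)], rng.normal(size=(6, 3)) * 0.05)
        r = rotation_matrix(np.array([0.0, 0.0, np.pi / 2]))
        t_true = RigidTransform(r, np.array([1e-3, 2e-3, 3e-3]))
        tgt = t_true.apply_to_pointset(src)
        t, rms = estimate_rigid_transform(src, tgt)
        assert np.abs(t.rotation - t_true.rotation).max() < 1e-12
        assert np.abs(t.translation - t_true.translation).max() < 1e-12
        assert rms < 1e-12

    def test_exact_for_arbitrary_proper_motions_and_reflection_prone_sets(
        self, rng
    ):
        """Noiseless recovery stays exact (< 1e-10) even on nearly planar
        clouds under 180-degree rotations, where an unconstrained SVD fit
        would pick a reflection."""
        for _ in range(100):
            n = rng.integers(3, 12)
            pts = rng.normal(size=(n, 3)) * 0.03
            pts[:, 2] *= 1e-6  # nearly planar: reflection-prone
            src = PointSet([f"p{i}" for i in range(n)], pts)
            angle = np.pi if rng.random() < 0.5 else rng.uniform(0, np.pi)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            t_true = RigidTransform(
                rotation_matrix(angle * axis), rng.normal(size=3) * 0.01
            )
            tgt = t_true.apply_to_pointset(src)
            t, rms = estimate_rigid_transform(src, tgt)
            assert np.linalg.det(t.rotation) > 0
            assert np.abs(t.rotation - t_true.rotation).max() < 1e-10
            assert np.abs(t.translation - t_true.translation).max() < 1e-10

    def test_noisy_residual_matches_dof_counting(self, rng):
        """With isotropic noise SD sigma on N targets the expected RMS
        residual is sigma * sqrt((3N - 6) / (3N)) (6 DoF absorbed by the
        fit); checked against the Monte-Carlo mean over replicates."""
        n, sigma, reps = 100, 1e-4, 300
        src = PointSet([f"p{i}" for i in range(n)], rng.normal(size=(n, 3)) * 0.05)
        # rms is over per-point distance norms: E[rms^2] = sigma^2 (3N-6)/N
        expected = sigma * np.sqrt(3.0 - 6.0 / n)
        rms_values = []
        for _ in range(reps):
            t_true = random_transform(rng)
            tgt = t_true.apply_to_pointset(src)
            tgt.coords = tgt.coords + rng.normal(size=(n, 3)) * sigma
            _, rms = estimate_rigid_transform(src, tgt)
            rms_values.append(rms)
        assert np.mean(rms_values) == pytest.approx(expected, rel=0.02)

    def test_degenerate_and_mismatched_inputs(self, rng):
        line = PointSet(["a", "b", "c"], np.outer([0.0, 1.0, 2.0], [1.0, 1.0, 0.0]))
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(line, line)
        two = PointSet(["a", "b"], rng.normal(size=(2, 3)))
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(two, two)
        src = PointSet(["a", "b", "c"], rng.normal(size=(3, 3)))
        other = PointSet(["a", "b", "x"], rng.normal(size=(3, 3)))
        with pytest.raises(InputError):
            estimate_rigid_transform(src, other)


class TestEulerDecompose:
    @pytest.mark.parametrize("seq", ["ZXY", "XYZ", "ZYX", "YXZ", "XZY", "YZX"])
    def test_identity_and_single_axis(self, seq):
        ang, flag = euler_decompose(np.eye(3), seq)
        assert not flag
        np.testing.assert_allclose(ang, 0.0, atol=1e-15)
        theta = 0.7
        v = np.zeros(3)
        v["XYZ".index(seq[0])] = theta
        ang, _ = euler_decompose(rotation_matrix(v), seq)
        np.testing.assert_allclose(ang, [theta, 0.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("seq", ["ZXY", "XYZ", "ZYX"])
    def test_compose_decompose_roundtrip(self, seq, rng):
        for _ in range(1000):
            r = random_rotation(rng)
            ang, flag = euler_decompose(r, seq)
            assert np.abs(euler_compose(ang, seq) - r).max() < 1e-9

    def test_gimbal_lock_sets_first_angle_to_zero(self):
        r = euler_compose([0.3, np.pi / 2, 0.2], "ZXY")
        ang, flag = euler_decompose(r, "ZXY")
        assert flag
        assert ang[0] == 0.0
        # the remaining angles still reproduce the rotation
        assert np.abs(euler_compose(ang, "ZXY") - r).max() < 1e-9

    def test_small_rotations_match_rotation_vector(self, rng):
        """The Euler angles agree with the rotation-vector components to
        first order: the difference is second-order (bounded by theta^2),
        hence relative error < 1e-3 once the rotation is small enough."""
        for _ in range(200):
            theta = np.radians(rng.uniform(0.01, 1.0))
            v = rng.normal(size=3)
            v *= theta / np.linalg.norm(v)
            ang, _ = euler_decompose(rotation_matrix(v), "ZXY")
            # ZXY ordering: first angle about Z, then X, then Y
            ref = np.array([v[2], v[0], v[1]])
            assert np.abs(ang - ref).max() < theta**2
        for _ in range(100):
            theta = np.radians(rng.uniform(0.001, 0.1))
            v = rng.normal(size=3)
            v *= theta / np.linalg.norm(v)
            ang, _ = euler_decompose(rotation_matrix(v), "ZXY")
            ref = np.array([v[2], v[0], v[1]])
            assert np.abs(ang - ref).max() < 1e-3 * theta

    def test_rotation_vector_roundtrip_includes_near_pi(self, rng):
        for angle in [1e-8, 0.1, 2.0, np.pi - 1e-8, np.pi]:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            r = rotation_matrix(angle * axis)
            r2 = rotation_matrix(rotation_vector(r))
            assert np.abs(r2 - r).max() < 1e-7


class TestMotionAboutJoint:
    def joint(self, rng=None, cor=(0.0, 0.0, 0.0), orientation=None):
        if orientation is None:
            orientation = np.eye(3) if rng is None else random_rotation(rng)
        return JointPose("L2-L3", np.asarray(cor), orientation)

    def test_identity_motion_gives_zeros(self, rng):
        m = motion_about_joint(RigidTransform.identity(), self.joint(rng))
        np.testing.assert_allclose(m.to_array(), 0.0, atol=1e-15)

    def test_pure_translation_along_joint_x(self, rng):
        j = self.joint(rng, cor=(0.01, 0.02, 0.03))
        t = RigidTransform(np.eye(3), j.orientation[:, 0] * 0.5e-3)
        m = motion_about_joint(t, j)
        assert m.t_ap == pytest.approx(0.5e-3, abs=1e-15)
        assert abs(m.t_is) < 1e-15 and abs(m.t_rl) < 1e-15
        assert abs(m.r_fe) < 1e-15

    def test_circular_motion_closed_form(self, rng):
        """Rotation theta about the joint Z axis through a point offset r
        along joint X: r_fe = theta and the joint-origin displacement is
        r * (1 - cos, -sin, 0) in joint axes."""
        for _ in range(20):
            j = self.joint(rng, cor=rng.normal(size=3) * 0.05)
            r_off, theta = rng.uniform(0.005, 0.05), rng.uniform(-1.0, 1.0)
            centre = j.cor + j.orientation[:, 0] * r_off
            axis = j.orientation[:, 2]
            rot = rotation_matrix(axis * theta)
            t = RigidTransform(rot, centre - rot @ centre)
            m = motion_about_joint(t, j)
            assert m.r_fe == pytest.approx(theta, abs=1e-9)
            assert m.t_ap == pytest.approx(r_off * (1 - np.cos(theta)), abs=1e-9)
            assert m.t_is == pytest.approx(-r_off * np.sin(theta), abs=1e-9)
            assert abs(m.t_rl) < 1e-9

    def test_equivariance_under_common_rigid_map(self, rng):
        """Moving both the motion and the joint by a common rigid map leaves
        the local six-DoF motion unchanged."""
        for _ in range(50):
            j = self.joint(rng, cor=rng.normal(size=3) * 0.05)
            t = random_transform(rng)
            g = random_transform(rng)
            m0 = motion_about_joint(t, j)
            t_g = g.compose(t).compose(g.inverse())
            j_g = JointPose(j.joint_id, g.apply(j.cor), g.rotation @ j.orientation)
            m1 = motion_about_joint(t_g, j_g)
            np.testing.assert_allclose(m1.to_array(), m0.to_array(), atol=1e-9)


class TestPointSetIO:
    def test_csv_and_json_roundtrip(self, rng, tmp_path):
        ps = PointSet([f"p{i}" for i in range(4)], rng.normal(size=(4, 3)) * 0.1)
        ps.to_csv(tmp_path / "ps.csv")
        back = PointSet.from_csv(tmp_path / "ps.csv")
        np.testing.assert_allclose(back.coords, ps.coords, atol=1e-12)
        ps.to_json(tmp_path / "ps.json")
        back = PointSet.from_json(tmp_path / "ps.json")
        np.testing.assert_allclose(back.coords, ps.coords, atol=1e-18)
        assert back.labels == ps.labels

    def test_validation(self):
        with pytest.raises(InputError):
            PointSet(["a", "a"], np.zeros((2, 3)))
        with pytest.raises(InputError):
            PointSet(["a"], [[np.nan, 0, 0]])
        with pytest.raises(InputError):
            PointSet([], np.zeros((0, 3)))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_wrench_free_transform_apply_matches_matrix(seed):
    """apply() agrees with the homogeneous-matrix action on points."""
    rng = np.random.default_rng(seed)
    t = random_transform(rng)
    pts = rng.normal(size=(7, 3))
    hom = np.c_[pts, np.ones(7)] @ t.matrix().T
    np.testing.assert_allclose(t.apply(pts), hom[:, :3], atol=1e-12)
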