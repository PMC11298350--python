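"""Multibody chain: inertia, bushing law, equilibrium and dynamics."""

import dataclasses

import numpy as np
import pytest
import trimesh

from ivjoint.errors import (
    AssemblyError,
    ConvergenceError,
    InputError,
    SingularJointError,
    TopologyError,
)
from ivjoint.frames import JointPose
from ivjoint.kinematics import MotionSixDoF, RigidTransform, motion_about_joint, rotation_matrix
from ivjoint.model import (
    BodySpec,
    BushingParams,
    LoadCase,
    ModelSpec,
    assemble_model,
    bushing_wrench,
    gravitational_settling_overshoot,
    mesh_inertial_properties,
    predicted_motion,
    simulate_dynamic,
    solve_quasi_static,
)


def single_bushing_model(bush=None, com=(0.0, 0.0, 0.0), gravity=(0, 0, 0)):
    bush = bush or BushingParams.literature_initial()
    ground = BodySpec("ground", 1.0, [0, -0.05, 0], np.eye(3) * 1e-4)
    body = BodySpec("body", 1.0, com, np.eye(3) * 1e-4)
    pose = JointPose("body-ground", [0, 0, 0], np.eye(3))
    return assemble_model([ground, body], [pose], bush, ground="ground",
                          gravity=gravity)


class TestMeshInertia:
    def test_cube_closed_form(self):
        """0.1 m cube at 1140 kg/m^3: mass 1.14 kg, I = m a^2 / 6."""
        cube = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        props = mesh_inertial_properties(cube, 1140.0)
        assert props["mass"] == pytest.approx(1.14, rel=1e-9)
        np.testing.assert_allclose(
            props["inertia"], np.eye(3) * 1.14 * 0.1**2 / 6, atol=1e-12
        )
        np.testing.assert_allclose(props["com"], 0.0, atol=1e-12)

    def test_translation_moves_com_not_inertia(self):
        cube = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        shifted = cube.copy()
        shifted.apply_translation([0.3, -0.2, 0.1])
        a = mesh_inertial_properties(cube, 1140.0)
        b = mesh_inertial_properties(shifted, 1140.0)
        np.testing.assert_allclose(b["com"] - a["com"], [0.3, -0.2, 0.1],
                                   atol=1e-12)
        np.testing.assert_allclose(b["inertia"], a["inertia"], atol=1e-12)

    def test_icosphere_converges_to_solid_sphere(self):
        """Refinement error vs the analytic 2/5 m r^2 decreases
        monotonically and is below 0.5 % at subdivision depth 4."""
        r, rho = 0.05, 1000.0
        m_exact = 4.0 / 3.0 * np.pi * r**3 * rho
        i_exact = 0.4 * m_exact * r**2
        errors = []
        for depth in (1, 2, 3, 4):
            sph = trimesh.creation.icosphere(subdivisions=depth, radius=r)
            props = mesh_inertial_properties(sph, rho)
            errors.append(abs(props["inertia"][0, 0] - i_exact) / i_exact)
        assert all(e2 < e1 for e1, e2 in zip(errors, errors[1:]))
        assert errors[-1] < 0.005

    def test_inverted_winding_corrected_with_warning(self):
        cube = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        cube.invert()
        with pytest.warns(UserWarning, match="winding"):
            props = mesh_inertial_properties(cube, 1140.0)
        assert props["mass"] == pytest.approx(1.14, rel=1e-9)

    def test_open_mesh_rejected(self):
        cube = trimesh.creation.box(extents=(0.1, 0.1, 0.1))
        open_mesh = trimesh.Trimesh(cube.vertices, cube.faces[:-2])
        with pytest.raises(TopologyError):
            mesh_inertial_properties(open_mesh, 1140.0)


class TestBushingWrench:
    def test_zero_motion_zero_wrench(self):
        w = bushing_wrench(MotionSixDoF(0, 0, 0, 0, 0, 0), np.zeros(6),
                           BushingParams.literature_initial())
        np.testing.assert_array_equal(w["force"], 0.0)
        np.testing.assert_array_equal(w["torque"], 0.0)

    def test_axial_hooke_arithmetic(self):
        """-0.5 mm axial compression at 110 kN/m restores +55 N on joint Y."""
        m = MotionSixDoF(0.0, -0.5e-3, 0.0, 0.0, 0.0, 0.0)
        w = bushing_wrench(m, np.zeros(6), BushingParams.literature_initial())
        np.testing.assert_allclose(w["force"], [0.0, 55.0, 0.0], atol=1e-12)

    def test_rotational_axes_mapping(self):
        p = BushingParams(1, 1, 1, k_lb=10, k_ar=20, k_fe=30)
        m = MotionSixDoF(0, 0, 0, r_fe=0.1, r_lb=0.2, r_ar=0.3)
        w = bushing_wrench(m, np.zeros(6), p)
        # torque axes X=LB, Y=AR, Z=FE
        np.testing.assert_allclose(w["torque"], [-2.0, -6.0, -3.0], atol=1e-12)

    def test_damping_matches_overdamped_transient_oracle(self):
        """A released single-mass axial displacement follows the analytic
        overdamped second-order solution, confirming the -c*rate term."""
        k, c, mass = 110_000.0, 1000.0, 1.0
        bush = BushingParams(k, k, k, 64, 268, 37, c_trans=c, c_rot=1.4)
        model = single_bushing_model(bush)
        # static preload then release: start from the F/k displacement
        load = LoadCase(axial_n=54.0, body="body", application_point=[0, 0, 0])
        st = solve_quasi_static(model, load)
        free = LoadCase(axial_n=0.0, body="body", application_point=[0, 0, 0])
        frames = simulate_dynamic(model, free, dt=0.002, t_end=0.05,
                                  initial=st, rtol=1e-10, atol=1e-13)
        x0 = st.transforms["body"].translation[1]
        lam = np.roots([mass, c, k])
        a = x0 * lam[1] / (lam[1] - lam[0])
        b = x0 - a
        for f in frames:
            expected = (a * np.exp(lam[0] * f.time)
                        + b * np.exp(lam[1] * f.time)).real
            assert f.transforms["body"].translation[1] == pytest.approx(
                expected, abs=5e-9
            )


class TestAssembly:
    def bodies(self, n=4):
        return [BodySpec(f"b{i}", 1.0, [0, 0.03 * i, 0], np.eye(3) * 1e-4)
                for i in range(n)]

    def poses(self, n=3):
        return [JointPose(f"b{i+1}-b{i}", [0, 0.03 * i + 0.015, 0], np.eye(3))
                for i in range(n)]

    def test_four_body_chain_valid(self):
        m = assemble_model(self.bodies(), self.poses(),
                           BushingParams.literature_initial(), ground="b0")
        assert m.ground_body == "b0"
        assert [j.child for j in m.joints] == ["b1", "b2", "b3"]

    def test_duplicate_child_rejected(self):
        from ivjoint.model import JointSpec

        bodies = self.bodies(3)
        bush = BushingParams.literature_initial()
        joints = [
            JointSpec("b0", "b2", self.poses(1)[0], bush),
            JointSpec("b1", "b2", self.poses(1)[0], bush),
        ]
        with pytest.raises(AssemblyError, match="same child"):
            ModelSpec(bodies, joints, "b0")

    def test_missing_ground_and_broken_chain(self):
        with pytest.raises(AssemblyError, match="ground"):
            ModelSpec(self.bodies(2), [], ground_body="nope")
        with pytest.raises(AssemblyError):
            assemble_model(self.bodies(3), self.poses(1),
                           BushingParams.literature_initial(), ground="b0")

    def test_point_mass_top_assembly_accepted(self):
        """1 kg point-mass top assembly with a 50 mm anterior CoM offset from
        the pot-marker centroid is accepted and echoed."""
        marker_centroid = np.array([0.0, 0.15, 0.0])
        com = marker_centroid + np.array([0.05, 0.0, 0.0])
        top = BodySpec("top", 1.0, com, np.eye(3) * 1e-4)
        bodies = self.bodies(2) + [top]
        poses = self.poses(1) + [JointPose("top-b1", [0, 0.05, 0], np.eye(3))]
        m = assemble_model(bodies, poses, BushingParams.literature_initial(),
                           ground="b0")
        assert m.body("top").mass == 1.0
        np.testing.assert_allclose(m.body("top").com, com)


class TestQuasiStatic:
    def test_zero_load_zero_gravity_identity(self):
        model = single_bushing_model()
        st = solve_quasi_static(model, None)
        assert st.converged
        assert st.residual_force_norm == 0.0
        t = st.transforms["body"]
        np.testing.assert_array_equal(t.translation, 0.0)

    def test_axial_closed_form_f_over_k(self):
        """54 N pure axial load on one 110 kN/m bushing: deflection
        F/k = 0.490909... mm, to better than 0.01 %."""
        model = single_bushing_model()
        load = LoadCase(axial_n=54.0, body="body", application_point=[0, 0, 0])
        st = solve_quasi_static(model, load)
        deflection_mm = -st.transforms["body"].translation[1] * 1e3
        assert deflection_mm == pytest.approx(54.0 / 110_000.0 * 1e3, rel=1e-4)

    def test_zero_stiffness_in_loaded_dof_raises(self):
        bush = BushingParams(24600, 0.0, 13500, 64, 268, 37)
        model = single_bushing_model(bush)
        load = LoadCase(axial_n=54.0, body="body", application_point=[0, 0, 0])
        with pytest.raises(SingularJointError):
            solve_quasi_static(model, load)

    def test_linear_regime_scaling(self, truth_default):
        """Halving the load and scaling the solution by two agrees within
        2 % while rotations stay below a degree."""
        model = truth_default.build_model()
        model = ModelSpec(model.bodies, model.joints, model.ground_body,
                          gravity=np.zeros(3))
        # small enough that the compressive (follower-load) softening of the
        # rotational DoF stays negligible
        load = dataclasses.replace(truth_default.load_case, axial_n=2.0)
        full = solve_quasi_static(model, load)
        half = solve_quasi_static(model, load, load_scale=0.5)
        for j in model.joints:
            mf = motion_about_joint(full.transforms[j.child], j.pose).to_array()
            mh = motion_about_joint(half.transforms[j.child], j.pose).to_array()
            assert np.degrees(np.abs(mf[3:])).max() < 1.0
            scale = np.abs(mf) > 1e-12
            np.testing.assert_allclose(2 * mh[scale], mf[scale], rtol=0.02)

    def test_solution_independent_of_initial_guess(self, truth_default):
        model = truth_default.build_model()
        load = truth_default.load_case
        a = solve_quasi_static(model, load)
        rng = np.random.default_rng(0)
        b = solve_quasi_static(model, load, x0=a.q + rng.normal(size=a.q.size) * 1e-3)
        for name in ("L1", "L2", "L3"):
            d = a.transforms[name].translation - b.transforms[name].translation
            assert np.abs(d).max() < 1e-9  # < 1e-6 mm

    def test_stiffer_flexion_never_rotates_more(self, truth_default):
        """|r_fe| at equilibrium is non-increasing in k_fe under the
        standard eccentric load."""
        prev = None
        for k_fe in (20.0, 30.0, 60.0, 120.0, 400.0):
            bush = truth_default.true_stiffness.with_values(k_fe=k_fe)
            model = truth_default.build_model(bushing=bush)
            st = solve_quasi_static(model, truth_default.load_case)
            r_fe = abs(motion_about_joint(
                st.transforms["L2"], model.joint_for_child("L2").pose
            ).r_fe)
            if prev is not None:
                assert r_fe <= prev + 1e-12
            prev = r_fe


class TestDynamics:
    def test_constant_load_settles_to_quasi_static(self):
        model = single_bushing_model()
        load = LoadCase(axial_n=54.0, body="body", application_point=[0, 0, 0],
                        profile="constant", duration=1.0)
        st = solve_quasi_static(model, load)
        frames = simulate_dynamic(model, load, dt=0.04, t_end=2.0,
                                  rtol=1e-9, atol=1e-12)
        final = frames[-1].transforms["body"].translation
        np.testing.assert_allclose(final, st.transforms["body"].translation,
                                   atol=1e-7)

    def test_energy_dissipates_without_load(self):
        model = single_bushing_model()
        load = LoadCase(axial_n=54.0, body="body", application_point=[0, 0, 0])
        st = solve_quasi_static(model, load)
        free = LoadCase(axial_n=0.0, body="body", application_point=[0, 0, 0])
        frames = simulate_dynamic(model, free, dt=0.01, t_end=0.3, initial=st,
                                  rtol=1e-9, atol=1e-12)
        energies = np.array([f.mechanical_energy for f in frames])
        assert np.all(np.diff(energies) <= 1e-12)

    def test_zero_damping_rejected(self):
        bush = BushingParams(24600, 110000, 13500, 64, 268, 37,
                             c_trans=0.0, c_rot=1.4)
        model = single_bushing_model(bush)
        load = LoadCase(axial_n=1.0, body="body", application_point=[0, 0, 0])
        with pytest.raises(InputError, match="damping"):
            simulate_dynamic(model, load)

    def test_gravitational_settling_artefact_flag(self, truth_default):
        """With gravity on, the early ramp response is dominated by the
        model settling under its own weight; with gravity off the response
        lags the ramp and the flag stays clear."""
        model = truth_default.build_model()
        load = dataclasses.replace(truth_default.load_case, profile="ramp")
        frames = simulate_dynamic(model, load, dt=0.04, t_end=1.0,
                                  rtol=1e-6, atol=1e-9)
        assert gravitational_settling_overshoot(frames, load, "L1")
        no_g = ModelSpec(model.bodies, model.joints, model.ground_body,
                         gravity=np.zeros(3))
        frames = simulate_dynamic(no_g, load, dt=0.04, t_end=1.0,
                                  rtol=1e-6, atol=1e-9)
        assert not gravitational_settling_overshoot(frames, load, "L1")


class TestPredictedMotion:
    def test_identity_state_gives_zeros(self, truth_default):
        from ivjoint.model import EquilibriumState

        model = truth_default.build_model()
        ident = {b.name: RigidTransform.identity() for b in model.bodies}
        st = EquilibriumState(ident, 0.0, 0.0, True)
        for m in predicted_motion(st, model).values():
            np.testing.assert_allclose(m.to_array(), 0.0, atol=1e-15)

    def test_pure_fe_rotation_of_one_vertebra(self, truth_default):
        from ivjoint.model import EquilibriumState

        model = truth_default.build_model()
        pose = model.joint_for_child("L2").pose
        theta = 0.02
        rot = rotation_matrix(pose.orientation[:, 2] * theta)
        t = RigidTransform(rot, pose.cor - rot @ pose.cor)
        ident = {b.name: RigidTransform.identity() for b in model.bodies}
        ident["L2"] = t
        motions = predicted_motion(
            EquilibriumState(ident, 0.0, 0.0, True), model
        )
        assert motions["L2"].r_fe == pytest.approx(theta, abs=1e-12)
        assert abs(motions["L3"].r_fe) < 1e-15
        assert abs(motions["L1"].r_fe) < 1e-15

    def test_random_states_match_conjugation_oracle(self, truth_default, rng):
        from ivjoint.model import EquilibriumState

        model = truth_default.build_model()
        for _ in range(20):
            transforms = {model.ground_body: RigidTransform.identity()}
            for j in model.joints:
                transforms[j.child] = RigidTransform(
                    rotation_matrix(rng.normal(size=3) * 0.05),
                    rng.normal(size=3) * 1e-3,
                )
            st = EquilibriumState(transforms, 0.0, 0.0, True)
            motions = predicted_motion(st, model)
            for j in model.joints:
                jm = j.pose.orientation
                t = transforms[j.child]
                r_local = jm.T @ t.rotation @ jm
                d_local = jm.T @ (t.rotation @ j.pose.cor + t.translation
                                  - j.pose.cor)
                got = motions[j.child]
                np.testing.assert_allclose(
                    [got.t_ap, got.t_is, got.t_rl], d_local, atol=1e-12
                )

    def test_unconverged_state_refused(self, truth_default):
        from ivjoint.model import EquilibriumState

        model = truth_default.build_model()
        st = EquilibriumState(
            {b.name: RigidTransform.identity() for b in model.bodies},
            1.0, 1.0, False,
        )
        with pytest.raises(ConvergenceError):
            predicted_motion(st, model)
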