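"""Synthetic analogue of the potted L1-L4 flexion experiment.

Generates a fully specified stand-in for the study's CT/DIC data: schematic
parametric vertebra meshes (elliptic-cylinder body plus a posterior block —
only landmarks, inertia and attachment points matter to the mechanics, mesh
realism is a non-goal), ground-truth landmarks and joint poses, ground-truth
bushing stiffnesses, pot geometry with tracking markers, the eccentric
compressive ramp load (54 N over 1 s), and simulated DIC-like measurements:
surface-point trajectories at 25 Hz, pot-marker trajectories, and noisy
per-vertebra rigid transforms (translation noise at the experimentally
reported uncertainties; rotation noise is a configurable placeholder).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import IVJointError, InputError
from .frames import (
    JointPose,
    LandmarkSet,
    PalpationModel,
    build_chain_poses,
    sample_landmark_sets,
)
from .kinematics import PointSet, RigidTransform, rotation_matrix
from .model import (
    BodySpec,
    BushingParams,
    LoadCase,
    ModelSpec,
    TrajectoryFrame,
    assemble_model,
    mesh_inertial_properties,
    simulate_dynamic,
    solve_quasi_static,
)

__all__ = [
    "SyntheticConfig",
    "NoiseModel",
    "SyntheticTruth",
    "ExperimentData",
    "make_synthetic_spine",
    "simulate_experiment",
    "perturb_palpation",
]

VERTEBRAE = ("L1", "L2", "L3", "L4")  # cranial to caudal


@dataclass
class NoiseModel:
    """Measurement noise applied to each vertebra's estimated transform.

    Translation SDs are per lab axis in mm (anterior-posterior and axial
    values are the experimentally reported DIC uncertainties; right-left
    reuses the AP value).  The rotational uncertainty was not reported and
    defaults to a small placeholder.  Palpation scatter is the resultant SD
    of the virtual-palpation landmark positions."""

    sd_trans_ap_mm: float = 0.0013
    sd_trans_is_mm: float = 8.1e-4
    sd_trans_rl_mm: float = 0.0013
    sd_rot_deg: float = 0.005
    palpation_resultant_mm: float = 2.9

    def __post_init__(self):
        for f in ("sd_trans_ap_mm", "sd_trans_is_mm", "sd_trans_rl_mm",
                  "sd_rot_deg", "palpation_resultant_mm"):
            if getattr(self, f) < 0:
                raise InputError(f"noise SD {f} must be >= 0")

    def translation_sd_m(self) -> np.ndarray:
        return np.array(
            [self.sd_trans_ap_mm, self.sd_trans_is_mm, self.sd_trans_rl_mm]
        ) / 1e3


@dataclass
class SyntheticConfig:
    """Geometry, loading and ground-truth parameters of the synthetic spine.

    Dimensions are schematic lumbar values (metres).  The true stiffnesses
    default to the order of the identified specimen values; the non-optimised
    DoF default to the literature initial estimates so that, with matched
    joint poses, the identification problem closes exactly."""

    body_half_ap: float = 0.0175
    body_half_rl: float = 0.021
    body_height: float = 0.028
    disc_gap: float = 0.010
    pedicle_halfwidth: float = 0.012
    posterior_block: tuple = (0.012, 0.024, 0.030)
    jitter_rot_deg: float = 1.0
    jitter_trans_mm: float = 0.5
    density_kg_m3: float = 1140.0
    # loading
    load_axial_n: float = 54.0
    load_rl_n: float = 0.0
    load_eccentricity_ap_m: float = 0.004
    ramp_duration_s: float = 1.0
    hold_time_s: float = 1.5
    # top assembly (point mass rigidly attached to the cranial vertebra)
    top_mass_kg: float = 1.0
    top_com_offset_ap_m: float = 0.0
    top_inertia_kg_m2: float = 1e-4
    # ground truth stiffness
    true_stiffness: BushingParams = field(
        default_factory=lambda: BushingParams(
            k_ap=25_000.0, k_is=440_000.0, k_rl=13_500.0,
            k_lb=64.0, k_ar=268.0, k_fe=30.0,
        )
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    n_surface_points: int = 60
    gravity_on: bool = True

    def __post_init__(self):
        for f in ("body_half_ap", "body_half_rl", "body_height", "disc_gap",
                  "density_kg_m3", "ramp_duration_s", "top_mass_kg"):
            if getattr(self, f) <= 0:
                raise InputError(f"config field {f} must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth for one synthetic specimen."""

    config: SyntheticConfig
    seed: int
    meshes: dict  # vertebra id -> trimesh.Trimesh (lab reference pose)
    landmarks: list[LandmarkSet]  # ordered cranial -> caudal (L1..L4)
    joint_poses: list[JointPose]  # [L1-L2, L2-L3, L3-L4]
    bodies: list[BodySpec]  # ordered ground -> cranial
    pot_markers: dict[str, PointSet]
    pot_reference_point: np.ndarray  # centre of bottom pot's upper surface (m)
    actuator_point: np.ndarray  # lab, body-fixed to the cranial body (m)
    load_case: LoadCase

    @property
    def true_stiffness(self) -> BushingParams:
        return self.config.true_stiffness

    @property
    def palpation_model(self) -> PalpationModel:
        return PalpationModel(self.config.noise.palpation_resultant_mm / 1e3)

    def chain_poses(self) -> list[JointPose]:
        """Joint poses ordered for assembly (caudal joint first)."""
        return list(reversed(self.joint_poses))

    def build_model(
        self,
        joint_poses: Sequence[JointPose] | None = None,
        bushing: BushingParams | None = None,
    ) -> ModelSpec:
        """Assemble the chain, optionally with candidate poses/stiffnesses.

        ``joint_poses`` may be given in either cranial-first ([L1-L2, L2-L3,
        L3-L4]) or assembly ([L3-L4, ...]) order; they are matched by id."""
        poses = self.chain_poses()
        if joint_poses is not None:
            by_id = {p.joint_id: p for p in joint_poses}
            if set(by_id) != {p.joint_id for p in poses}:
                raise InputError("candidate poses must cover every joint id")
            poses = [by_id[p.joint_id] for p in poses]
        bush = bushing if bushing is not None else self.true_stiffness
        gravity = None if self.config.gravity_on else np.zeros(3)
        return assemble_model(self.bodies, poses, bush, ground=self.bodies[0].name,
                              gravity=gravity)


def _vertebra_mesh(cfg: SyntheticConfig):
    import trimesh

    body = trimesh.creation.cylinder(
        radius=1.0, height=cfg.body_height, sections=48
    )
    v = body.vertices.copy()
    v[:, 0] *= cfg.body_half_ap
    v[:, 1] *= cfg.body_half_rl
    body.vertices = v
    # cylinder axis Z -> anatomical Y (superior)
    rx = np.eye(4)
    rx[:3, :3] = rotation_matrix(np.array([-np.pi / 2, 0.0, 0.0]))
    body.apply_transform(rx)

    bx, by, bz = cfg.posterior_block
    block = trimesh.creation.box(extents=(bx, by, bz))
    block.apply_translation([-(cfg.body_half_ap + 0.001 + bx / 2), 0.0, 0.0])
    return trimesh.util.concatenate([body, block])


def _local_landmarks(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    h2 = cfg.body_height / 2
    return {
        "sup_endplate_centre": np.array([0.0, h2, 0.0]),
        "inf_endplate_centre": np.array([0.0, -h2, 0.0]),
        "pedicle_base_left": np.array(
            [-cfg.body_half_ap, 0.0, -cfg.pedicle_halfwidth]
        ),
        "pedicle_base_right": np.array(
            [-cfg.body_half_ap, 0.0, cfg.pedicle_halfwidth]
        ),
    }


def make_synthetic_spine(
    cfg: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticTruth:
    """Build a synthetic L1-L4 specimen with ground truth.

    Vertebrae are stacked with configurable disc gaps and given a small,
    seeded rigid jitter (pose variability); landmarks are placed analytically
    on each mesh and the true joint poses derive from them through the same
    frame construction the pipeline uses, so the two are consistent by
    construction.
    """
    import trimesh

    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    pitch = cfg.body_height + cfg.disc_gap
    local_lm = _local_landmarks(cfg)
    base_mesh = _vertebra_mesh(cfg)

    meshes: dict = {}
    landmark_sets: list[LandmarkSet] = []
    jitters: dict[str, RigidTransform] = {}
    # cranial (L1, index 3 in stack height) down to caudal (L4 at y=0)
    for idx, vid in enumerate(VERTEBRAE):
        level = len(VERTEBRAE) - 1 - idx  # L1 -> 3 ... L4 -> 0
        centre = np.array([0.0, level * pitch, 0.0])
        rot = rotation_matrix(
            rng.normal(0.0, np.radians(cfg.jitter_rot_deg), size=3)
        )
        shift = rng.normal(0.0, cfg.jitter_trans_mm / 1e3, size=3)
        # jitter rotates about the vertebra centre
        t = RigidTransform(rot, centre + shift - rot @ centre, validate=False)
        jitters[vid] = t

        m = base_mesh.copy()
        m.apply_translation(centre)
        tm = np.eye(4)
        tm[:3, :3] = t.rotation
        tm[:3, 3] = t.translation
        m.apply_transform(tm)
        meshes[vid] = m
        landmark_sets.append(
            LandmarkSet(vid, {n: p + centre for n, p in local_lm.items()}).transformed(t)
        )

    # overlap guard: consecutive meshes must not intersect
    for a, b in zip(VERTEBRAE[:-1], VERTEBRAE[1:]):
        lo = meshes[a].bounds[0][1]
        hi = meshes[b].bounds[1][1]
        if hi > lo:
            raise IVJointError(
                f"synthetic geometry error: {a} and {b} overlap "
                f"(reduce jitter or increase disc_gap)"
            )

    joint_poses = build_chain_poses(landmark_sets)

    # pots
    l4_mesh, l1_mesh = meshes["L4"], meshes["L1"]
    pot_top_y = float(l4_mesh.bounds[0][1]) - 0.002
    pot_reference_point = np.array([0.0, pot_top_y, 0.0])
    top_pot_base_y = float(l1_mesh.bounds[1][1]) + 0.002
    marker_y = top_pot_base_y + 0.012
    half = 0.05
    corners = np.array(
        [[half, 0, half], [half, 0, -half], [-half, 0, half], [-half, 0, -half]]
    )
    pot_markers = {
        "bottom": PointSet(
            [f"bot_{i}" for i in range(4)],
            corners + pot_reference_point,
            "lab",
        ),
        "top": PointSet(
            [f"top_{i}" for i in range(4)],
            corners + np.array([0.0, marker_y, 0.0]),
            "lab",
        ),
    }
    marker_centroid = pot_markers["top"].coords.mean(axis=0)
    actuator_point = marker_centroid + np.array(
        [cfg.load_eccentricity_ap_m, 0.0, 0.0]
    )

    # bodies
    bodies = []
    pot_props = mesh_inertial_properties(l4_mesh, cfg.density_kg_m3)
    bodies.append(
        BodySpec("pot_L4", mass=pot_props["mass"] + 2.0,
                 com=pot_props["com"], inertia=pot_props["inertia"],
                 landmark_ref=landmark_sets[3])
    )
    for vid, lm in (("L3", landmark_sets[2]), ("L2", landmark_sets[1])):
        p = mesh_inertial_properties(meshes[vid], cfg.density_kg_m3)
        bodies.append(
            BodySpec(vid, p["mass"], p["com"], p["inertia"], landmark_ref=lm)
        )
    l1p = mesh_inertial_properties(l1_mesh, cfg.density_kg_m3)
    top_com = marker_centroid + np.array([cfg.top_com_offset_ap_m, 0.0, 0.0])
    m_tot = l1p["mass"] + cfg.top_mass_kg
    com = (l1p["mass"] * l1p["com"] + cfg.top_mass_kg * top_com) / m_tot
    inertia = _parallel_axis(l1p["inertia"], l1p["mass"], l1p["com"] - com)
    inertia = inertia + _parallel_axis(
        np.eye(3) * cfg.top_inertia_kg_m2, cfg.top_mass_kg, top_com - com
    )
    bodies.append(
        BodySpec("L1", m_tot, com, inertia, landmark_ref=landmark_sets[0])
    )

    load_case = LoadCase(
        axial_n=cfg.load_axial_n,
        rl_n=cfg.load_rl_n,
        body="L1",
        application_point=actuator_point,
        profile="ramp",
        duration=cfg.ramp_duration_s,
    )

    return SyntheticTruth(
        config=cfg,
        seed=seed,
        meshes=meshes,
        landmarks=landmark_sets,
        joint_poses=joint_poses,
        bodies=bodies,
        pot_markers=pot_markers,
        pot_reference_point=pot_reference_point,
        actuator_point=actuator_point,
        load_case=load_case,
    )


def _parallel_axis(inertia: np.ndarray, mass: float, d: np.ndarray) -> np.ndarray:
    return inertia + mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))


# ---------------------------------------------------------------------------
# simulated experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentData:
    """Simulated DIC-like measurements from one loading experiment."""

    times: np.ndarray
    frames: list[TrajectoryFrame]  # quasi-static sequence or transient states
    surface_points: dict  # vertebra -> (labels, (n_frames, n_pts, 3) m)
    pot_marker_trajectory: dict  # pot -> (n_frames, n_markers, 3) m
    measured_transforms: dict[str, RigidTransform]  # final frame, noisy
    true_transforms: dict[str, RigidTransform]  # final frame, noise-free
    load_components: list[dict]  # per frame: time, ap/axial/rl force (N)
    mode: str


def simulate_experiment(
    truth: SyntheticTruth, mode: str = "quasistatic", seed: int = 0
) -> ExperimentData:
    """Run the forward model at the true stiffnesses and sample measurements.

    quasistatic: a sequence of equilibrium solves at the 25 Hz ramp load
    levels, then the held full load.  dynamic: transient integration of the
    ramp.  Measured per-vertebra transforms are the final-frame transforms
    corrupted with the transform-level noise model (point-level noise for
    registration testing is applied by the caller via ``surface_points``).
    """
    if mode not in ("quasistatic", "dynamic"):
        raise InputError(f"unknown mode {mode!r}")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    model = truth.build_model()
    load = truth.load_case
    dt = 0.04
    t_end = load.duration + cfg.hold_time_s

    if mode == "dynamic":
        frames = simulate_dynamic(model, load, dt=dt, t_end=t_end)
    else:
        times = np.arange(int(round(t_end / dt)) + 1) * dt
        frames = []
        warm = None
        for k, t in enumerate(times):
            if k == 0:
                # the reference (pre-release) configuration: the DIC
                # reference image to which the model geometry is registered
                transforms = {
                    b.name: RigidTransform.identity() for b in model.bodies
                }
                frames.append(TrajectoryFrame(float(t), transforms, 0.0, 0.0))
                continue
            st = solve_quasi_static(model, load, x0=warm,
                                    load_scale=load.scale_at(t))
            warm = st.q
            frames.append(
                TrajectoryFrame(float(t), st.transforms, 0.0, 0.0)
            )
    times = np.array([f.time for f in frames])

    # body-fixed surface points sampled from each vertebra mesh
    surface_points = {}
    for vid in ("L1", "L2", "L3"):
        verts = truth.meshes[vid].vertices
        idx = rng.choice(len(verts), size=min(cfg.n_surface_points, len(verts)),
                         replace=False)
        pts0 = verts[idx]
        traj = np.empty((len(frames), len(idx), 3))
        for k, f in enumerate(frames):
            traj[k] = f.transforms[vid].apply(pts0)
        surface_points[vid] = ([f"{vid}_{i}" for i in range(len(idx))], traj)

    pot_traj = {}
    for pot, ps in truth.pot_markers.items():
        traj = np.empty((len(frames), len(ps), 3))
        carrier = "L1" if pot == "top" else model.ground_body
        for k, f in enumerate(frames):
            traj[k] = f.transforms[carrier].apply(ps.coords)
        pot_traj[pot] = traj

    true_transforms = {
        vid: frames[-1].transforms[vid] for vid in ("L1", "L2", "L3")
    }
    sd_t = cfg.noise.translation_sd_m()
    sd_r = np.radians(cfg.noise.sd_rot_deg)
    measured = {}
    for vid, t in true_transforms.items():
        dr = rotation_matrix(rng.normal(0.0, sd_r, size=3))
        dtv = rng.normal(0.0, 1.0, size=3) * sd_t
        measured[vid] = RigidTransform(dr @ t.rotation, t.translation + dtv,
                                       validate=False)

    # load decomposition by the (final) top-pot orientation; AP forced to 0
    f_full = load.force_vector()
    load_components = []
    r_pot = true_transforms["L1"].rotation
    for t in times:
        f = load.scale_at(float(t)) * f_full
        axial = -float(r_pot[:, 1] @ f)  # compression positive
        rl = float(r_pot[:, 2] @ f)
        load_components.append(
            {"time_s": float(t), "f_ap_n": 0.0, "f_axial_n": axial, "f_rl_n": rl}
        )

    return ExperimentData(
        times=times,
        frames=frames,
        surface_points=surface_points,
        pot_marker_trajectory=pot_traj,
        measured_transforms=measured,
        true_transforms=true_transforms,
        load_components=load_components,
        mode=mode,
    )


def perturb_palpation(
    truth: SyntheticTruth, resultant_sd: float, n: int, seed: int
) -> list[list[LandmarkSet]]:
    """n operator-like landmark collections around the true landmarks
    (resultant_sd in metres; delegates to the Latin-Hypercube sampler)."""
    return sample_landmark_sets(
        truth.landmarks, PalpationModel(resultant_sd), n, seed
    )


# ---------------------------------------------------------------------------
# dataset directory export
# ---------------------------------------------------------------------------

def export_dataset(truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Write a self-contained dataset directory (STL meshes, landmark JSON,
    truth.json with poses/stiffness/load in mm-and-degree display units)."""
    from .frames import save_landmarks_json

    out = Path(out_dir)
    (out / "meshes").mkdir(parents=True, exist_ok=True)
    for vid, mesh in truth.meshes.items():
        mesh.export(out / "meshes" / f"{vid}.stl")
    save_landmarks_json(truth.landmarks, out / "landmarks.json")
    payload = {
        "seed": truth.seed,
        "config": _config_dict(truth.config),
        "joint_poses": [p.to_dict() for p in truth.joint_poses],
        "true_stiffness": truth.true_stiffness.to_dict(),
        "pot_reference_point_mm": [float(v) for v in truth.pot_reference_point * 1e3],
        "actuator_point_mm": [float(v) for v in truth.actuator_point * 1e3],
        "load": {
            "axial_n": truth.load_case.axial_n,
            "rl_n": truth.load_case.rl_n,
            "profile": truth.load_case.profile,
            "duration_s": truth.load_case.duration,
        },
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=1))


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["true_stiffness"] = cfg.true_stiffness.to_dict()
    d["noise"] = asdict(cfg.noise)
    return d
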