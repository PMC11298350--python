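"""Vertebral and joint reference frames from palpated landmarks.

A vertebra's anatomical frame is built from four virtually palpated
landmarks: the superior and inferior endplate centres and the left/right
pedicle bases.  The joint (IVJ) frame between two adjacent vertebrae places
its centre of rotation at the midpoint of the facing endplate centres and its
orientation at the geodesic mean of the two vertebral frames.

Inter-operator palpation variability is modelled as an isotropic trivariate
normal per landmark with per-axis SD = resultant / sqrt(3); perturbed landmark
collections are drawn with per-coordinate Latin-Hypercube stratification so a
small sample already covers the marginals evenly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import ndtri

from .errors import DegenerateGeometryError, InputError
from .kinematics import RigidTransform, _check_rotation, rotation_matrix, rotation_vector

__all__ = [
    "LANDMARK_NAMES",
    "LandmarkSet",
    "VertebraFrame",
    "JointPose",
    "PalpationModel",
    "build_vertebra_frame",
    "build_joint_pose",
    "sample_landmark_sets",
    "dispersion_stats",
]

LANDMARK_NAMES = (
    "sup_endplate_centre",
    "inf_endplate_centre",
    "pedicle_base_left",
    "pedicle_base_right",
)


@dataclass
class LandmarkSet:
    """Named anatomical landmarks of one vertebra (positions in metres)."""

    vertebra_id: str
    points: dict[str, np.ndarray]

    def __post_init__(self):
        missing = [n for n in LANDMARK_NAMES if n not in self.points]
        if missing:
            raise InputError(f"missing landmarks: {missing}")
        pts = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise InputError(f"landmark {name} is not finite")
            pts[name] = p
        self.points = pts
        sep = np.linalg.norm(
            pts["sup_endplate_centre"] - pts["inf_endplate_centre"]
        )
        if sep <= 1e-6:
            raise InputError("endplate centres coincide")

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(
            self.vertebra_id, {n: t.apply(p) for n, p in self.points.items()}
        )

    # -- I/O: JSON {vertebra_id, landmarks:{name:[mm]}}; flat CSV mirror --
    def to_json_dict(self) -> dict:
        return {
            "vertebra_id": self.vertebra_id,
            "landmarks": {
                n: [float(v) for v in p * 1e3] for n, p in self.points.items()
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "LandmarkSet":
        return cls(
            d["vertebra_id"],
            {n: np.asarray(p) / 1e3 for n, p in d["landmarks"].items()},
        )


def save_landmarks_json(sets: Sequence[LandmarkSet], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([s.to_json_dict() for s in sets], indent=1)
    )


def load_landmarks_json(path: str | Path) -> list[LandmarkSet]:
    return [
        LandmarkSet.from_json_dict(d) for d in json.loads(Path(path).read_text())
    ]


def save_landmarks_csv(sets: Sequence[LandmarkSet], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["vertebra", "label", "x_mm", "y_mm", "z_mm"])
        for s in sets:
            for name, p in s.points.items():
                w.writerow([s.vertebra_id, name] + [f"{v:.9g}" for v in p * 1e3])


def load_landmarks_csv(path: str | Path) -> list[LandmarkSet]:
    per_vert: dict[str, dict] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            per_vert.setdefault(row["vertebra"], {})[row["label"]] = (
                np.array([float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])])
                / 1e3
            )
    return [LandmarkSet(v, pts) for v, pts in per_vert.items()]


@dataclass
class VertebraFrame:
    """Anatomical frame: origin (m) and column axes X anterior, Y superior, Z right."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = _check_rotation(self.axes, tol=1e-9)


@dataclass
class JointPose:
    """One IVJ's centre of rotation and axis orientation in the lab frame."""

    joint_id: str
    cor: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        self.cor = np.asarray(self.cor, dtype=float).reshape(3)
        self.orientation = _check_rotation(self.orientation, tol=1e-9)

    def transformed(self, t: RigidTransform) -> "JointPose":
        return JointPose(
            self.joint_id, t.apply(self.cor), t.rotation @ self.orientation
        )

    def to_dict(self) -> dict:
        return {
            "joint_id": self.joint_id,
            "cor_mm": [float(v) for v in self.cor * 1e3],
            "orientation": [float(v) for v in self.orientation.ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointPose":
        return cls(
            d["joint_id"],
            np.asarray(d["cor_mm"]) / 1e3,
            np.asarray(d["orientation"]).reshape(3, 3),
        )


@dataclass
class PalpationModel:
    """Isotropic trivariate normal palpation scatter.

    resultant_sd is the root-mean-square Euclidean (resultant) dispersion in
    metres (default 2.9 mm); the per-axis SD is resultant_sd / sqrt(3).
    Per-landmark overrides map landmark name -> resultant SD.
    """

    resultant_sd: float = 2.9e-3
    per_landmark: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.resultant_sd < 0 or any(v < 0 for v in self.per_landmark.values()):
            raise InputError("palpation SD must be >= 0")

    def axis_sd(self, landmark: str) -> float:
        return self.per_landmark.get(landmark, self.resultant_sd) / np.sqrt(3.0)


def build_vertebra_frame(lm: LandmarkSet) -> VertebraFrame:
    """ISB-style anatomical frame from the four vertebral landmarks.

    Origin: midpoint of the endplate centres.  Y: inferior -> superior
    endplate centre.  Provisional Z: left -> right pedicle base.
    X = unit(Y x Z_prov); Z = X x Y.
    """
    sup = lm.points["sup_endplate_centre"]
    inf = lm.points["inf_endplate_centre"]
    left = lm.points["pedicle_base_left"]
    right = lm.points["pedicle_base_right"]

    origin = (sup + inf) / 2.0
    y = sup - inf
    y = y / np.linalg.norm(y)
    z_prov = right - left
    nz = np.linalg.norm(z_prov)
    if nz <= 1e-12:
        raise DegenerateGeometryError("pedicle bases coincide")
    z_prov = z_prov / nz
    x = np.cross(y, z_prov)
    nx = np.linalg.norm(x)
    if nx < 1e-4:  # Y parallel to provisional Z
        raise DegenerateGeometryError(
            "superior axis is parallel to the pedicle line"
        )
    x = x / nx
    z = np.cross(x, y)
    return VertebraFrame(origin, np.column_stack([x, y, z]))


def _geodesic_mean(r_a: np.ndarray, r_b: np.ndarray) -> np.ndarray:
    """Midpoint of the geodesic from r_a to r_b on SO(3)."""
    rel = r_a.T @ r_b
    half = rotation_matrix(rotation_vector(rel) / 2.0)
    return r_a @ half


def build_joint_pose(
    lower: tuple[VertebraFrame, LandmarkSet],
    upper: tuple[VertebraFrame, LandmarkSet],
) -> JointPose:
    """Joint pose between two adjacent vertebrae.

    CoR: midpoint between the lower vertebra's superior endplate centre and
    the upper vertebra's inferior endplate centre.  Orientation: geodesic
    mean of the two vertebral frames.
    """
    lo_frame, lo_lm = lower
    up_frame, up_lm = upper
    cor = (
        lo_lm.points["sup_endplate_centre"] + up_lm.points["inf_endplate_centre"]
    ) / 2.0
    orientation = _geodesic_mean(lo_frame.axes, up_frame.axes)
    return JointPose(f"{up_lm.vertebra_id}-{lo_lm.vertebra_id}", cor, orientation)


def build_chain_poses(landmarks: Sequence[LandmarkSet]) -> list[JointPose]:
    """Joint poses for a cranial-to-caudal ordered chain of vertebrae.

    ``landmarks[0]`` is the most cranial vertebra; returns one pose per
    adjacent pair, e.g. [L1-L2, L2-L3, L3-L4] for an L1..L4 chain.
    """
    frames = [build_vertebra_frame(lm) for lm in landmarks]
    poses = []
    for upper_i in range(len(landmarks) - 1):
        lower_i = upper_i + 1
        poses.append(
            build_joint_pose(
                (frames[lower_i], landmarks[lower_i]),
                (frames[upper_i], landmarks[upper_i]),
            )
        )
    return poses


def sample_landmark_sets(
    mean: Sequence[LandmarkSet],
    model: PalpationModel,
    n: int,
    seed: int | np.random.Generator,
) -> list[list[LandmarkSet]]:
    """Draw *n* palpation-perturbed landmark collections by Latin Hypercube.

    Each scalar coordinate of each landmark is stratified independently into
    *n* equal-probability strata of its normal marginal; one draw per stratum,
    stratum order permuted per coordinate.  Coordinates are processed in a
    fixed documented order (vertebra order as given, landmark order as in
    LANDMARK_NAMES, axes x, y, z) from a single seeded generator stream, so a
    given seed is reproducible across platforms.
    """
    if n < 1:
        raise InputError("n must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out_points = []  # per vertebra: dict name -> (n, 3)
    for lm in mean:
        per_lm = {}
        sd = {name: model.axis_sd(name) for name in LANDMARK_NAMES}
        for name in LANDMARK_NAMES:
            cols = np.empty((n, 3))
            for ax in range(3):
                perm = rng.permutation(n)
                u = rng.random(n)
                q = (perm + u) / n
                cols[:, ax] = lm.points[name][ax] + sd[name] * ndtri(q)
            per_lm[name] = cols
        out_points.append(per_lm)
    collections = []
    for i in range(n):
        collections.append(
            [
                LandmarkSet(
                    lm.vertebra_id,
                    {name: out_points[v][name][i] for name in LANDMARK_NAMES},
                )
                for v, lm in enumerate(mean)
            ]
        )
    return collections


def dispersion_stats(samples: Sequence[Sequence[LandmarkSet]]) -> dict:
    """Dispersion of sampled landmark collections about their per-landmark mean.

    Returns per-axis SD (m), the resultant RMS Euclidean distance (m) --
    sqrt(mean over samples and landmarks of the squared distance to the
    per-landmark mean) -- and a per-landmark breakdown.
    """
    if len(samples) < 2:
        raise InputError("dispersion requires >= 2 samples")
    n_vert = len(samples[0])
    sq_dists = []
    axis_devs = []
    per_landmark: dict[str, float] = {}
    for v in range(n_vert):
        vid = samples[0][v].vertebra_id
        for name in LANDMARK_NAMES:
            pts = np.array([s[v].points[name] for s in samples])  # (n, 3)
            mean = pts.mean(axis=0)
            dev = pts - mean
            d2 = np.sum(dev**2, axis=1)
            sq_dists.append(d2)
            axis_devs.append(dev)
            per_landmark[f"{vid}:{name}"] = float(np.sqrt(d2.mean()))
    all_d2 = np.concatenate(sq_dists)
    all_dev = np.vstack(axis_devs)
    return {
        "per_axis_sd": all_dev.std(axis=0, ddof=0),
        "rms_distance": float(np.sqrt(all_d2.mean())),
        "per_landmark": per_landmark,
    }
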