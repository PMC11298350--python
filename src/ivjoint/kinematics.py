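"""Rigid-transform algebra, SVD point-set registration, and joint-frame motion.

Conventions used repo-wide (right-handed, ISB-style): X anterior, Y superior
(cranial), Z right.  Flexion-extension is rotation about Z, lateral bending
about X, axial rotation about Y.  Internal units are SI (m, rad); file I/O is
in mm (and degrees where angles appear).

The six-DoF motion of a vertebra "about" an intervertebral joint is the
conjugation of its lab-frame rigid motion into the joint frame,
``T_local = J^-1 . T . J``: the translation part is the displacement of the
joint origin expressed in joint axes, and the rotation part is decomposed with
an intrinsic Z-X-Y Euler sequence (flexion-extension first, the dominant
experimental motion, then lateral bending, then axial rotation).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InputError

__all__ = [
    "RigidTransform",
    "PointSet",
    "MotionSixDoF",
    "estimate_rigid_transform",
    "motion_about_joint",
    "euler_decompose",
    "euler_compose",
    "rotation_matrix",
    "rotation_vector",
]

_AXES = {"X": 0, "Y": 1, "Z": 2}

#: ordering of the six motion components used throughout tabular output
MOTION_FIELDS = ("t_ap", "t_is", "t_rl", "r_fe", "r_lb", "r_ar")


def _check_rotation(r: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise InputError(f"rotation must be 3x3, got {r.shape}")
    if not np.all(np.isfinite(r)):
        raise InputError("rotation contains non-finite entries")
    if np.abs(r.T @ r - np.eye(3)).max() > tol:
        raise InputError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise InputError("rotation matrix has determinant -1 (reflection)")
    return r


def rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rodrigues map: rotation vector (rad) -> 3x3 rotation matrix."""
    v = np.asarray(rotvec, dtype=float)
    angle = np.linalg.norm(v)
    if angle < 1e-12:
        # second-order series keeps the map smooth through zero
        k = _skew(v)
        return np.eye(3) + k + 0.5 * (k @ k)
    axis = v / angle
    k = _skew(axis)
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def rotation_vector(r: np.ndarray) -> np.ndarray:
    """Inverse Rodrigues map (angle in [0, pi])."""
    r = np.asarray(r, dtype=float)
    cos_a = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos_a)
    if angle < 1e-10:
        return np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]]) / 2.0
    if np.pi - angle < 1e-6:
        # near pi: extract axis from the symmetric part
        m = (r + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(m), 0.0, None))
        # fix signs using off-diagonals
        i = int(np.argmax(axis))
        if axis[i] > 0:
            axis = m[:, i] / axis[i]
            axis = axis / np.linalg.norm(axis)
        return angle * axis
    axis = np.array([r[2, 1] - r[1, 2], r[0, 2] - r[2, 0], r[1, 0] - r[0, 1]])
    return angle * axis / (2.0 * np.sin(angle))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array(
        [[0.0, -v[2], v[1]], [v[2], 0.0, -v[0]], [-v[1], v[0], 0.0]]
    )


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid map ``x -> R x + t`` between frames.

    rotation : (3, 3) orthonormal, det +1
    translation : (3,) in metres
    """

    rotation: np.ndarray
    translation: np.ndarray
    validate: bool = field(default=True, repr=False, compare=False)

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if self.validate:
            r = _check_rotation(r)
            if not np.all(np.isfinite(t)):
                raise InputError("translation contains non-finite entries")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), validate=False)

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise InputError("homogeneous matrix must be 4x4")
        return cls(m[:3, :3], m[:3, 3])

    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self . other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            validate=False,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, validate=False)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (N, 3) or (3,) through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def apply_to_pointset(self, ps: "PointSet") -> "PointSet":
        return PointSet(list(ps.labels), self.apply(ps.coords), ps.frame_id)

    def to_dict(self) -> dict:
        """JSON form: row-major rotation, translation in mm."""
        return {
            "rotation": [float(x) for x in self.rotation.ravel()],
            "translation_mm": [float(x) for x in self.translation * 1e3],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            np.asarray(d["rotation"], dtype=float).reshape(3, 3),
            np.asarray(d["translation_mm"], dtype=float) / 1e3,
        )


@dataclass
class PointSet:
    """Labelled point cloud (coords in metres, a lab or body frame id)."""

    labels: list[str]
    coords: np.ndarray
    frame_id: str = "lab"

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.labels = [str(x) for x in self.labels]
        if len(self.labels) != self.coords.shape[0]:
            raise InputError("labels and coords length mismatch")
        if len(self.labels) < 1:
            raise InputError("PointSet requires at least one point")
        if len(set(self.labels)) != len(self.labels):
            raise InputError("PointSet labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise InputError("PointSet coordinates must be finite")

    def __len__(self) -> int:
        return len(self.labels)

    def subset(self, labels: Sequence[str]) -> "PointSet":
        idx = [self.labels.index(l) for l in labels]
        return PointSet(list(labels), self.coords[idx], self.frame_id)

    # -- I/O: CSV columns label,x_mm,y_mm,z_mm; JSON mirror -------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "x_mm", "y_mm", "z_mm"])
            for lab, xyz in zip(self.labels, self.coords * 1e3):
                w.writerow([lab, f"{xyz[0]:.9g}", f"{xyz[1]:.9g}", f"{xyz[2]:.9g}"])

    @classmethod
    def from_csv(cls, path: str | Path, frame_id: str = "lab") -> "PointSet":
        labels, coords = [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                labels.append(row["label"])
                coords.append(
                    [float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])]
                )
        return cls(labels, np.asarray(coords) / 1e3, frame_id)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "frame_id": self.frame_id,
            "points": {
                lab: [float(v) for v in xyz]
                for lab, xyz in zip(self.labels, self.coords * 1e3)
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PointSet":
        payload = json.loads(Path(path).read_text())
        labels = list(payload["points"])
        coords = np.asarray([payload["points"][k] for k in labels]) / 1e3
        return cls(labels, coords, payload.get("frame_id", "lab"))


@dataclass
class MotionSixDoF:
    """A vertebra's rigid motion expressed in its inferior joint's axes.

    Translations in metres along the joint X (anterior-posterior),
    Y (inferior-superior) and Z (right-left) axes; rotations in radians:
    flexion-extension about Z, lateral bending about X, axial rotation about Y.
    """

    t_ap: float
    t_is: float
    t_rl: float
    r_fe: float
    r_lb: float
    r_ar: float
    joint_id: str = ""

    def __post_init__(self):
        for name in ("r_fe", "r_lb", "r_ar"):
            a = getattr(self, name)
            if not (-np.pi < a <= np.pi + 1e-12):
                # wrap into (-pi, pi]
                a = (a + np.pi) % (2 * np.pi) - np.pi
                if a == -np.pi:
                    a = np.pi
                setattr(self, name, float(a))

    def to_array(self) -> np.ndarray:
        """Components ordered (t_ap, t_is, t_rl, r_fe, r_lb, r_ar), SI."""
        return np.array(
            [self.t_ap, self.t_is, self.t_rl, self.r_fe, self.r_lb, self.r_ar]
        )

    def to_display(self) -> dict:
        """mm / degrees for tabular output."""
        return {
            "t_ap_mm": self.t_ap * 1e3,
            "t_is_mm": self.t_is * 1e3,
            "t_rl_mm": self.t_rl * 1e3,
            "r_fe_deg": np.degrees(self.r_fe),
            "r_lb_deg": np.degrees(self.r_lb),
            "r_ar_deg": np.degrees(self.r_ar),
        }


def estimate_rigid_transform(
    source: PointSet, target: PointSet
) -> tuple[RigidTransform, float]:
    """Least-squares rigid registration source -> target (Kabsch, via SVD).

    Reflections are suppressed by forcing det(R) = +1.  Returns the transform
    and the RMS post-fit point distance in metres.

    Raises
    ------
    InputError
        if the label sets differ.
    DegenerateGeometryError
        if fewer than 3 points or the source points are collinear.
    """
    if set(source.labels) != set(target.labels):
        raise InputError("source and target point sets must share labels")
    if len(source) < 3:
        raise DegenerateGeometryError("rigid registration needs >= 3 points")
    tgt = target.subset(source.labels)

    p = source.coords
    q = tgt.coords
    cp = p.mean(axis=0)
    cq = q.mean(axis=0)
    pc = p - cp
    qc = q - cq

    s = np.linalg.svd(pc, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise DegenerateGeometryError("source points are collinear")

    h = pc.T @ qc
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cq - r @ cp

    resid = q - (p @ r.T + t)
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RigidTransform(r, t, validate=False), rms


def euler_compose(angles: Iterable[float], sequence: str = "ZXY") -> np.ndarray:
    """Compose an intrinsic Euler rotation R = R_s1(a1) R_s2(a2) R_s3(a3)."""
    sequence = sequence.upper()
    r = np.eye(3)
    for ax, ang in zip(sequence, angles):
        v = np.zeros(3)
        v[_AXES[ax]] = ang
        r = r @ rotation_matrix(v)
    return r


def euler_decompose(
    rotation: np.ndarray, sequence: str = "ZXY"
) -> tuple[np.ndarray, bool]:
    """Intrinsic Tait-Bryan Euler decomposition of an orthonormal rotation.

    Returns (angles, gimbal_lock_flag).  Within 1e-6 rad of gimbal lock
    (middle angle at +/- pi/2) the first angle is set to 0 and the flag is
    raised; the remaining two angles then reproduce the rotation.
    """
    r = _check_rotation(rotation)
    sequence = sequence.upper()
    if len(sequence) != 3 or len(set(sequence)) != 3:
        raise InputError("sequence must be a permutation of X, Y, Z")
    i, j, k = (_AXES[c] for c in sequence)
    # parity of the axis permutation
    eps = 1.0 if (j - i) % 3 == 1 else -1.0

    # middle angle: sin(b) = eps * R[i, k]
    sb = np.clip(eps * r[i, k], -1.0, 1.0)
    b = np.arcsin(sb)

    if np.pi / 2 - abs(b) < 1e-6:
        # gimbal lock: fix a = 0, recover c from the residual rotation
        bvec = np.zeros(3)
        bvec[j] = b
        rem = rotation_matrix(bvec).T @ r
        c = float(rotation_vector(rem)[k])
        return np.array([0.0, b, c]), True

    a = np.arctan2(-eps * r[j, k], r[k, k])
    c = np.arctan2(-eps * r[i, j], r[i, i])
    return np.array([a, b, c]), False


def _euler_zxy(r: np.ndarray) -> tuple[float, float, float]:
    """Fast intrinsic Z-X-Y extraction (fe, lb, ar); no validation.

    Used in solver inner loops; falls back to the general routine at lock.
    """
    sb = r[2, 1]
    if abs(sb) > 0.999999:
        ang, _ = euler_decompose(r, "ZXY")
        return float(ang[0]), float(ang[1]), float(ang[2])
    fe = np.arctan2(-r[0, 1], r[1, 1])
    lb = np.arcsin(min(1.0, max(-1.0, sb)))
    ar = np.arctan2(-r[2, 0], r[2, 2])
    return float(fe), float(lb), float(ar)


def motion_about_joint(vertebra_motion: RigidTransform, joint) -> MotionSixDoF:
    """Re-express a lab-frame vertebral motion in a joint's frame.

    ``T_local = J^-1 . T . J`` where J maps joint coordinates to the lab.
    Translations are the joint-origin displacement in joint axes; rotations
    are the intrinsic Z-X-Y decomposition (fe, lb, ar).
    """
    rj = _check_rotation(joint.orientation)
    cj = np.asarray(joint.cor, dtype=float).reshape(3)
    r = vertebra_motion.rotation
    t = vertebra_motion.translation
    r_local = rj.T @ r @ rj
    t_local = rj.T @ (r @ cj + t - cj)
    fe, lb, ar = _euler_zxy(r_local)
    return MotionSixDoF(
        t_ap=float(t_local[0]),
        t_is=float(t_local[1]),
        t_rl=float(t_local[2]),
        r_fe=fe,
        r_lb=lb,
        r_ar=ar,
        joint_id=getattr(joint, "joint_id", ""),
    )
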