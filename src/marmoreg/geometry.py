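"""Rigid-body transform algebra and point-set fitting.

World coordinates are right-handed RAS millimetres (+X right, +Y anterior,
+Z superior).  Euler angles follow a fixed-axis (extrinsic) convention,
applied X then Y then Z::

    R = Rz(yaw) @ Ry(roll) @ Rx(pitch)

with pitch about X (left-right), roll about Y (anterior-posterior) and yaw
about Z (inferior-superior), all in degrees.  This convention is used for
every angle reported by the package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, FormatError, InputError

__all__ = [
    "RigidTransform",
    "EulerAngles",
    "PointSet",
    "kabsch_fit",
    "euler_compose",
    "euler_decompose",
    "mean_transform",
    "dedrift",
    "point_to_line_distance",
    "read_transform",
    "write_transform",
]

#: orthonormality tolerance for rotation matrices
ORTHONORMAL_TOL = 1e-9
#: middle-angle magnitude (degrees) beyond which Euler decomposition is flagged
GIMBAL_WARN_DEG = 89.0


def _check_rotation(rotation: np.ndarray, tol: float = ORTHONORMAL_TOL) -> np.ndarray:
    rotation = np.asarray(rotation, dtype=float)
    if rotation.shape != (3, 3):
        raise InputError(f"rotation must be 3x3, got {rotation.shape}")
    err = np.abs(rotation @ rotation.T - np.eye(3)).max()
    if err > tol:
        raise InputError(f"rotation is not orthonormal (max deviation {err:.3e})")
    if np.linalg.det(rotation) < 0:
        raise InputError("rotation has determinant -1 (reflection, not a rotation)")
    return rotation


@dataclass(frozen=True)
class RigidTransform:
    """A 6-DOF world-to-world rigid mapping ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if not np.all(np.isfinite(t)):
            raise InputError("translation must be finite")
        object.__setattr__(self, "translation", t)

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise FormatError(f"expected a 4x4 matrix, got {matrix.shape}")
        return cls(matrix[:3, :3], matrix[:3, 3])

    @classmethod
    def from_euler_translation(
        cls, angles: "EulerAngles | Sequence[float]", translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        if not isinstance(angles, EulerAngles):
            angles = EulerAngles(*angles)
        return cls(euler_compose(angles), np.asarray(translation, dtype=float))

    # -- algebra --------------------------------------------------------
    def as_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ other`` (apply *other* first, then *self*)."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def rotation_vector(self) -> np.ndarray:
        """Axis-angle (log-map) representation of the rotation, radians."""
        from scipy.spatial.transform import Rotation

        return Rotation.from_matrix(self.rotation).as_rotvec()

    def euler(self) -> "EulerAngles":
        return euler_decompose(self)

    def is_close(self, other: "RigidTransform", tol: float = 1e-9) -> bool:
        return (
            np.abs(self.rotation - other.rotation).max() <= tol
            and np.abs(self.translation - other.translation).max() <= tol
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        e = self.euler()
        return (
            f"RigidTransform(pitch={e.pitch:.4g}°, roll={e.roll:.4g}°, "
            f"yaw={e.yaw:.4g}°, t={np.array2string(self.translation, precision=4)})"
        )


@dataclass(frozen=True)
class EulerAngles:
    """Fixed-axis X-then-Y-then-Z Euler angles in degrees."""

    pitch: float
    roll: float
    yaw: float
    gimbal_warning: bool = False

    def as_tuple(self) -> tuple:
        return (self.pitch, self.roll, self.yaw)


@dataclass(frozen=True)
class PointSet:
    """Labelled 3D points in world millimetres."""

    labels: tuple
    coords: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        coords = np.asarray(self.coords, dtype=float).reshape(len(labels), 3)
        if len(labels) < 1:
            raise InputError("PointSet needs at least one point")
        if len(set(labels)) != len(labels):
            raise InputError("PointSet labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise InputError("PointSet coordinates must be finite")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, label) -> np.ndarray:
        return self.coords[self.labels.index(label)]

    def transformed(self, t: RigidTransform) -> "PointSet":
        return PointSet(self.labels, t.apply(self.coords))

    def reordered(self, labels: Sequence) -> "PointSet":
        idx = [self.labels.index(l) for l in labels]
        return PointSet(tuple(labels), self.coords[idx])


def _collinearity_ratio(coords: np.ndarray) -> float:
    """Second singular value of centred coords, relative to the first."""
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if s[0] == 0:
        return 0.0
    return s[1] / s[0]


def kabsch_fit(source: PointSet, target: PointSet) -> RigidTransform:
    """Least-squares rigid transform mapping *source* onto *target*.

    Solves ``argmin_T Σ‖T(s_i) − t_i‖²`` over rotations+translations (no
    scaling or shear) with the SVD of the cross-covariance, including the
    proper-rotation (det +1) correction.

    Raises
    ------
    InputError
        if the label sets differ.
    DegenerateGeometryError
        if fewer than 3 points or the source points are collinear.
    """
    if set(source.labels) != set(target.labels):
        raise InputError(
            f"label mismatch: {sorted(map(str, source.labels))} vs "
            f"{sorted(map(str, target.labels))}"
        )
    target = target.reordered(source.labels)
    if len(source) < 3:
        raise DegenerateGeometryError(f"need >= 3 points, got {len(source)}")
    if _collinearity_ratio(source.coords) < 1e-9:
        raise DegenerateGeometryError("source points are collinear")

    p = source.coords
    q = target.coords
    pc = p.mean(axis=0)
    qc = q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # re-orthonormalise to keep downstream 1e-9 invariants after float error
    uu, _, vvt = np.linalg.svd(rotation)
    rotation = uu @ vvt
    translation = qc - rotation @ pc
    return RigidTransform(rotation, translation)


def fit_residuals(t: RigidTransform, source: PointSet, target: PointSet) -> np.ndarray:
    """Per-point Euclidean distances after applying *t* to *source*."""
    target = target.reordered(source.labels)
    return np.linalg.norm(t.apply(source.coords) - target.coords, axis=1)


def euler_compose(angles: "EulerAngles | Sequence[float]") -> np.ndarray:
    """Rotation matrix for fixed-axis X-then-Y-then-Z angles (degrees)."""
    if isinstance(angles, EulerAngles):
        pitch, roll, yaw = angles.as_tuple()
    else:
        pitch, roll, yaw = angles
    a, b, c = np.deg2rad([pitch, roll, yaw])
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cc, sc = np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    return rz @ ry @ rx


def euler_decompose(t: "RigidTransform | np.ndarray") -> EulerAngles:
    """Decompose a rotation into fixed-axis X-then-Y-then-Z angles (degrees).

    The middle (Y) angle is the gimbal axis of this convention; results are
    flagged with ``gimbal_warning`` when it comes within 1° of ±90°.
    """
    r = t.rotation if isinstance(t, RigidTransform) else _check_rotation(t)
    # R = Rz Ry Rx  =>  R[2,0] = -sin(roll)
    sb = np.clip(-r[2, 0], -1.0, 1.0)
    roll = np.arcsin(sb)
    if np.cos(roll) > 1e-12:
        pitch = np.arctan2(r[2, 1], r[2, 2])
        yaw = np.arctan2(r[1, 0], r[0, 0])
    else:  # gimbal lock: only pitch±yaw is determined; put it all in pitch
        pitch = np.arctan2(-r[1, 2], r[1, 1])
        yaw = 0.0
    angles = np.rad2deg([pitch, roll, yaw])
    warn = abs(angles[1]) > GIMBAL_WARN_DEG
    return EulerAngles(angles[0], angles[1], angles[2], gimbal_warning=bool(warn))


def mean_transform(ts: Sequence[RigidTransform], tol: float = 1e-12, max_iter: int = 100) -> RigidTransform:
    """Fréchet mean of rigid transforms.

    Translation is the arithmetic mean.  Rotation is the Karcher (log-space)
    mean, iterated to the fixed point ``mean_i log(M⁻¹ R_i) = 0``; for the
    small rotations this tool handles (< 30°) a couple of iterations
    converge well below 1e-12.
    """
    from scipy.spatial.transform import Rotation

    ts = list(ts)
    if not ts:
        raise InputError("mean_transform of an empty list")
    translation = np.mean([t.translation for t in ts], axis=0)
    m = ts[0].rotation
    for _ in range(max_iter):
        residual = np.mean(
            [Rotation.from_matrix(m.T @ t.rotation).as_rotvec() for t in ts], axis=0
        )
        if np.linalg.norm(residual) < tol:
            break
        m = m @ Rotation.from_rotvec(residual).as_matrix()
    u, _, vt = np.linalg.svd(m)
    return RigidTransform(u @ vt, translation)


def dedrift(ts: Sequence[RigidTransform]) -> list:
    """Compose each transform with the inverse mean so the set is centred.

    The returned list satisfies ``mean_transform(out) == identity`` within
    1e-9 (exactly the Karcher fixed-point property).
    """
    ts = list(ts)
    inv_mean = mean_transform(ts).inverse()
    return [inv_mean.compose(t) for t in ts]


def point_to_line_distance(p, line_point, line_dir) -> float:
    """Perpendicular distance (mm) from point *p* to the line through
    *line_point* with direction *line_dir*."""
    p = np.asarray(p, dtype=float).reshape(3)
    lp = np.asarray(line_point, dtype=float).reshape(3)
    d = np.asarray(line_dir, dtype=float).reshape(3)
    norm = np.linalg.norm(d)
    if norm == 0:
        raise InputError("line direction must be non-zero")
    return float(np.linalg.norm(np.cross(p - lp, d / norm)))


# -- transform files ----------------------------------------------------

def write_transform(t: RigidTransform, path, fmt: str = "auto") -> None:
    """Write a transform as a plain-text 4x4 row-major matrix (``.mat``/
    ``.txt``) or as JSON carrying rotation, translation and Euler angles."""
    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "matrix"
    if fmt == "matrix":
        np.savetxt(path, t.as_matrix(), fmt="%.12g")
    elif fmt == "json":
        e = t.euler()
        payload = {
            "rotation": t.rotation.tolist(),
            "translation": t.translation.tolist(),
            "euler_degrees": {"pitch": e.pitch, "roll": e.roll, "yaw": e.yaw},
            "euler_convention": "fixed-axis X-then-Y-then-Z (R = Rz@Ry@Rx), RAS world",
        }
        path.write_text(json.dumps(payload, indent=2))
    else:
        raise InputError(f"unknown transform format {fmt!r}")


def read_transform(path) -> RigidTransform:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        try:
            return RigidTransform(
                np.asarray(payload["rotation"]), np.asarray(payload["translation"])
            )
        except (KeyError, InputError) as exc:
            raise FormatError(f"bad transform JSON {path}: {exc}") from exc
    try:
        matrix = np.loadtxt(path)
    except ValueError as exc:
        raise FormatError(f"cannot parse transform matrix {path}: {exc}") from exc
    if matrix.shape != (4, 4):
        raise FormatError(f"{path}: expected 4x4 matrix, got {matrix.shape}")
    if np.abs(matrix[3] - [0, 0, 0, 1]).max() > 1e-9:
        raise FormatError(f"{path}: last row must be [0 0 0 1]")
    try:
        return RigidTransform.from_matrix(matrix)
    except InputError as exc:
        raise FormatError(f"{path}: {exc}") from exc
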