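"""Anatomical coordinate frames (AC-PC and image-based stereotactic).

A frame is represented by the rigid transform taking scanner world
coordinates into frame coordinates.  Sign convention for reported frame
bias: positive pitch tips the frontal (anterior, +Y) side downwards.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .errors import DegenerateGeometryError, InputError
from .geometry import EulerAngles, PointSet, RigidTransform, kabsch_fit

__all__ = [
    "FrameName",
    "LandmarkSet",
    "FrameDefinition",
    "FrameBias",
    "fit_acpc_frame",
    "fit_stereotactic_frame",
    "frame_bias",
    "landmark_fit_bias",
    "read_landmarks_csv",
    "write_landmarks_csv",
]

ACPC_REQUIRED = ("AC", "PC")
STEREO_REQUIRED = ("ear_canal_L", "ear_canal_R", "infraorbital_L", "infraorbital_R")
OPTIONAL_CRANIAL = ("bregma", "inion", "rhinion", "zygion_L", "zygion_R")


class FrameName(str, Enum):
    ACPC = "ACPC"
    STEREOTACTIC = "STEREOTACTIC"
    DEVICE = "DEVICE"


@dataclass
class LandmarkSet:
    """Named anatomical points in world millimetres."""

    points: Dict[str, np.ndarray]

    def __post_init__(self):
        clean = {}
        for name, p in self.points.items():
            p = np.asarray(p, dtype=float).reshape(3)
            if not np.all(np.isfinite(p)):
                raise InputError(f"landmark {name!r} has non-finite coordinates")
            clean[name] = p
        self.points = clean
        for left, right in (("ear_canal_L", "ear_canal_R"),
                            ("infraorbital_L", "infraorbital_R")):
            if left in clean and right in clean and np.allclose(clean[left], clean[right]):
                raise InputError(f"{left} and {right} coincide")

    def __contains__(self, name) -> bool:
        return name in self.points

    def __getitem__(self, name) -> np.ndarray:
        return self.points[name]

    @property
    def names(self) -> list:
        return list(self.points)

    def require(self, names) -> None:
        missing = [n for n in names if n not in self.points]
        if missing:
            raise InputError(f"missing required landmarks: {missing}")

    def subset(self, names) -> "PointSet":
        return PointSet(list(names), np.array([self.points[n] for n in names]))

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet({n: t.apply(p) for n, p in self.points.items()})


@dataclass
class FrameDefinition:
    name: FrameName
    to_frame: RigidTransform           # scanner world -> frame world
    landmarks: LandmarkSet
    origin_definition: str = ""

    def world_to_frame(self, points: np.ndarray) -> np.ndarray:
        return self.to_frame.apply(points)


@dataclass(frozen=True)
class FrameBias:
    rotation: EulerAngles
    translation: np.ndarray
    from_frame: str
    to_frame: str
    transform: RigidTransform

    def inverse(self) -> "FrameBias":
        inv = self.transform.inverse()
        return FrameBias(inv.euler(), inv.translation, self.to_frame,
                         self.from_frame, inv)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what} is degenerate (zero length)")
    return v / n


def _frame_from_axes(x, y, z, origin, name, landmarks, origin_definition) -> FrameDefinition:
    rotation = np.vstack([x, y, z])          # rows = frame axes in world coords
    transform = RigidTransform(rotation, -rotation @ origin)
    return FrameDefinition(name, transform, landmarks, origin_definition)


def fit_acpc_frame(lm: LandmarkSet, midsagittal_points: PointSet) -> FrameDefinition:
    """AC-PC native frame: origin at AC, +Y along PC->AC (anterior), the
    midsagittal plane X = 0 oriented so the supplied midsagittal points have
    zero mean X, +Z superior completing a right-handed frame.

    In the output frame AC maps to (0,0,0) and PC to (0, -|AC-PC|, 0).
    """
    lm.require(ACPC_REQUIRED)
    ac, pc = lm["AC"], lm["PC"]
    if np.allclose(ac, pc):
        raise DegenerateGeometryError("AC and PC coincide")
    y = _unit(ac - pc, "AC-PC line")

    mean_off = midsagittal_points.coords.mean(axis=0) - ac
    perp = mean_off - (mean_off @ y) * y
    if np.linalg.norm(perp) < 1e-9:
        raise DegenerateGeometryError(
            "midsagittal points are collinear with the AC-PC line")
    z = _unit(perp, "midsagittal constraint")   # superior, off the AC-PC line
    x = np.cross(y, z)
    return _frame_from_axes(x, y, z, ac, FrameName.ACPC, lm,
                            "origin at AC centre; +Y along PC->AC")


def fit_stereotactic_frame(lm: LandmarkSet) -> FrameDefinition:
    """Image-based stereotactic frame.

    The interaural line (left to right ear-canal centre) defines the X
    axis; the horizontal zero plane (Z = 0) is the least-squares plane
    constrained to contain the interaural line while passing as close as
    possible to the two infra-orbital points; the origin is the interaural
    midpoint; +Y points anterior, towards the infra-orbital side.
    """
    lm.require(STEREO_REQUIRED)
    ear_l, ear_r = lm["ear_canal_L"], lm["ear_canal_R"]
    origin = 0.5 * (ear_l + ear_r)
    x = _unit(ear_r - ear_l, "interaural line")

    offs = np.array([lm["infraorbital_L"] - origin, lm["infraorbital_R"] - origin])
    e = offs - np.outer(offs @ x, x)            # components perpendicular to X
    if np.linalg.norm(e, axis=1).max() < 1e-9:
        raise DegenerateGeometryError(
            "infra-orbital points are collinear with the interaural line")
    # least-squares plane normal n ⊥ x minimising Σ (n·e_i)²: the smaller
    # principal axis of e within the plane perpendicular to x
    basis = _perp_basis(x)
    proj = e @ basis.T                           # (2 points, 2 components)
    _, _, vt = np.linalg.svd(proj, full_matrices=True)
    n2 = vt[-1]                                  # direction of least spread
    z = n2 @ basis
    y = np.cross(z, x)
    if y @ e.mean(axis=0) < 0:                   # +Y anterior (infra-orbital side)
        z, y = -z, -y
    return _frame_from_axes(x, y, z, origin, FrameName.STEREOTACTIC, lm,
                            "origin at interaural midpoint; Z=0 through the "
                            "interaural line and infra-orbital ridge")


def _perp_basis(x: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the plane perpendicular to x."""
    seed = np.array([0.0, 0.0, 1.0]) if abs(x[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(x, seed), "perpendicular basis")
    v = np.cross(x, u)
    return np.vstack([u, v])


def frame_bias(a: FrameDefinition, b: FrameDefinition) -> FrameBias:
    """Rigid bias between two frames sharing the same scanner world:
    ``a.to_frame ∘ b.to_frame⁻¹`` decomposed into Euler angles + translation.

    ``frame_bias(a, b)`` is the exact inverse of ``frame_bias(b, a)``.
    """
    t = a.to_frame.compose(b.to_frame.inverse())
    return FrameBias(t.euler(), t.translation, b.name.value, a.name.value, t)


def landmark_fit_bias(pairs_in_frame_a: PointSet, pairs_in_frame_b: PointSet) -> FrameBias:
    """Rigid bias between two frames from the same labelled landmarks
    expressed in each: Kabsch fit a -> b, decomposed."""
    t = kabsch_fit(pairs_in_frame_a, pairs_in_frame_b)
    return FrameBias(t.euler(), t.translation, "frame_a", "frame_b", t)


# -- landmark CSV (name,x,y,z with header) -------------------------------

def read_landmarks_csv(path) -> LandmarkSet:
    points = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"name", "x", "y", "z"} <= set(
                map(str.lower, reader.fieldnames)):
            raise InputError(f"{path}: landmark CSV needs a name,x,y,z header")
        lower = {f.lower(): f for f in reader.fieldnames}
        for row in reader:
            points[row[lower["name"]]] = np.array(
                [float(row[lower[c]]) for c in "xyz"])
    if not points:
        raise InputError(f"{path}: no landmarks found")
    return LandmarkSet(points)


def write_landmarks_csv(lm: LandmarkSet, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "x", "y", "z"])
        for name, p in lm.points.items():
            writer.writerow([name, f"{p[0]:.6g}", f"{p[1]:.6g}", f"{p[2]:.6g}"])
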