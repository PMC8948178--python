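"""Volume data model, NIfTI I/O, thresholding and rigid resampling.

A :class:`Volume` is a 3D scalar grid plus a NIfTI-style centre-of-voxel
affine mapping voxel indices to world millimetres.  CT volumes follow the
Hounsfield convention (air -1000, water 0); MR intensities are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, InputError
from .geometry import RigidTransform

__all__ = [
    "Modality",
    "Volume",
    "LabelMask",
    "read_volume",
    "write_volume",
    "threshold_mask",
    "resample_rigid",
]


class Modality(str, Enum):
    CT = "CT"
    T1w = "T1w"
    T2w = "T2w"
    LABEL = "LABEL"


#: out-of-field fill value per modality
BACKGROUND = {Modality.CT: -1000.0, Modality.T1w: 0.0, Modality.T2w: 0.0, Modality.LABEL: 0.0}


@dataclass
class Volume:
    data: np.ndarray
    affine: np.ndarray
    modality: Modality = Modality.CT

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise InputError(f"volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise FormatError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is singular")
        self.modality = Modality(self.modality)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Column norms of the affine: voxel edge lengths in mm."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def background(self) -> float:
        return BACKGROUND[self.modality]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def world_bounds(self) -> np.ndarray:
        """(2, 3) array of min/max world coordinates over the 8 grid corners."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1) for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        w = self.voxel_to_world(corners)
        return np.stack([w.min(axis=0), w.max(axis=0)])

    def copy_with(self, **kwargs) -> "Volume":
        return replace(self, **kwargs)


class LabelMask(Volume):
    """Integer-labelled volume sharing grid and affine with a parent Volume."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InputError("LabelMask data must be integer-typed")
        if self.data.min() < 0:
            raise InputError("LabelMask labels must be non-negative")
        self.modality = Modality.LABEL


def read_volume(path, modality: "Modality | str | None" = None) -> Volume:
    """Read a NIfTI-1 volume; world coordinates come from its affine (mm)."""
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or abs(np.linalg.det(np.asarray(affine)[:3, :3])) < 1e-12:
        raise FormatError(f"{path}: missing or singular affine")
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    if modality is None:
        modality = _guess_modality(path)
    return Volume(data, np.asarray(affine, dtype=float), Modality(modality))


def _guess_modality(path) -> Modality:
    name = Path(path).name.lower()
    for tag, modality in (("t1", Modality.T1w), ("t2", Modality.T2w),
                          ("label", Modality.LABEL), ("mask", Modality.LABEL)):
        if tag in name:
            return modality
    return Modality.CT


def write_volume(v: Volume, path) -> None:
    img = nib.Nifti1Image(v.data, v.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def threshold_mask(v: Volume, lo: float, hi: float = np.inf) -> LabelMask:
    """Binary mask of voxels with intensity in ``[lo, hi)``."""
    if not lo < hi:
        raise InputError(f"threshold window invalid: lo={lo} >= hi={hi}")
    mask = (v.data >= lo) & (v.data < hi)
    return LabelMask(mask.astype(np.uint8), v.affine, Modality.LABEL)


_INTERP_ORDER = {"nearest": 0, "trilinear": 1, "spline": 3}


def resample_rigid(
    v: Volume,
    t: RigidTransform,
    reference: Volume,
    interp: str = "trilinear",
) -> Volume:
    """Resample *v* onto the grid of *reference* under the world mapping *t*.

    *t* maps the world of *v* into the world of *reference* (the usual
    moving-to-fixed direction): the output voxel at reference index ``i``
    samples *v* at ``t⁻¹(A_ref @ i)``.  Out-of-field samples are filled
    with the modality background (CT -1000, MR 0).  LABEL volumes are
    always resampled with nearest-neighbour.
    """
    if interp not in _INTERP_ORDER:
        raise InputError(f"unknown interpolation {interp!r}")
    order = _INTERP_ORDER[interp]
    if v.modality is Modality.LABEL:
        order = 0

    # voxel(ref) -> world(ref) -> world(v) -> voxel(v), one affine overall
    m = np.linalg.inv(v.affine) @ t.inverse().as_matrix() @ reference.affine
    idx = np.indices(reference.shape, dtype=float).reshape(3, -1)
    src = m[:3, :3] @ idx + m[:3, 3:4]
    out = ndimage.map_coordinates(
        v.data.astype(float), src, order=order, mode="constant", cval=v.background
    ).reshape(reference.shape)
    if v.modality is Modality.LABEL:
        out = out.astype(v.data.dtype)
    return Volume(out, reference.affine.copy(), v.modality)
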