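"""Marker-based fiducial registration (MBFR).

Pipeline: detect markers in both modalities, establish correspondence from
pairwise distances, fit a rigid transform (Kabsch), and score the result
with the marker registration error

    MRE = sqrt((d1² + d2² + ... + dn²) / n)

over post-registration centroid distances.  A registration is 'failed'
when the MRE exceeds the failure threshold (default 1 mm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InputError,
    MarmoregError,
    RegistrationStageError,
)
from .geometry import PointSet, RigidTransform, kabsch_fit
from .markers import MarkerSet, detect_markers, match_markers
from .volumes_io import Volume

__all__ = [
    "MBFRConfig",
    "RegistrationStatus",
    "RegistrationMethod",
    "RegistrationResult",
    "CohortSummary",
    "compute_mre",
    "run_mbfr",
    "summarize_cohort",
]


class RegistrationStatus(str, Enum):
    OK = "ok"
    FAILED = "failed"


class RegistrationMethod(str, Enum):
    MBFR = "MBFR"
    MBFR_BBR = "MBFR+BBR"
    OTHER = "other"


@dataclass
class MBFRConfig:
    """Detection and registration settings for the MBFR pipeline."""

    ct_marker_threshold: float = 800.0        # HU
    mr_marker_percentile: float = 99.5        # intensity percentile for MR
    min_marker_mm3: float = 2.0               # cavity is ~6.3 mm³ (2.0 dia x 2.0 mm)
    max_marker_mm3: float = 20.0
    match_tol_mm: float = 0.5
    failure_threshold_mm: float = 1.0
    max_detections: int = 12                  # keep the largest components
    leave_one_out: bool = False

    def voxel_window(self, v: Volume) -> tuple:
        vox_mm3 = float(np.prod(v.voxel_sizes))
        return (max(1, int(np.floor(self.min_marker_mm3 / vox_mm3))),
                int(np.ceil(self.max_marker_mm3 / vox_mm3)))


@dataclass
class RegistrationResult:
    transform: RigidTransform
    per_marker_distance: np.ndarray       # mm, one entry per matched marker
    mre: float                            # mm
    n_markers: int
    status: RegistrationStatus
    method: RegistrationMethod = RegistrationMethod.MBFR
    marker_labels: tuple = ()
    mre_leave_one_out: Optional[float] = None
    min_cost: Optional[float] = None      # set when BBR refinement follows

    def __post_init__(self):
        self.per_marker_distance = np.asarray(self.per_marker_distance, dtype=float)
        recomputed = float(np.sqrt(np.mean(self.per_marker_distance ** 2)))
        if abs(recomputed - self.mre) > 1e-12 + 1e-9 * abs(self.mre):
            raise InputError(
                f"inconsistent result: mre={self.mre} but distances give {recomputed}")

    def to_dict(self) -> dict:
        return {
            "transform": self.transform.as_matrix().tolist(),
            "per_marker_distance_mm": self.per_marker_distance.tolist(),
            "mre_mm": self.mre,
            "n_markers": self.n_markers,
            "status": self.status.value,
            "method": self.method.value,
            "marker_labels": list(self.marker_labels),
            "mre_leave_one_out_mm": self.mre_leave_one_out,
            "min_cost": self.min_cost,
        }

    def write_report(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class CohortSummary:
    n_total: int
    n_failed: int
    failure_probability: float
    mre_mean: float                  # over all results
    mre_sd: float
    mre_mean_ok: Optional[float]     # over non-failed results only
    mre_sd_ok: Optional[float]


def compute_mre(registered: PointSet, reference: PointSet) -> tuple:
    """Root-mean-square of Euclidean distances between matched labelled
    points.  Returns ``(mre, per_marker_distances)`` in mm."""
    if set(registered.labels) != set(reference.labels):
        raise InputError("compute_mre: label mismatch between point sets")
    reference = reference.reordered(registered.labels)
    d = np.linalg.norm(registered.coords - reference.coords, axis=1)
    return float(np.sqrt(np.mean(d ** 2))), d


def _status(mre: float, threshold: float) -> RegistrationStatus:
    return RegistrationStatus.FAILED if mre > threshold else RegistrationStatus.OK


def result_from_points(
    fitted: RigidTransform,
    source: PointSet,
    target: PointSet,
    cfg: Optional[MBFRConfig] = None,
    method: RegistrationMethod = RegistrationMethod.MBFR,
) -> RegistrationResult:
    """Assemble a RegistrationResult from a fitted transform and matched points."""
    cfg = cfg or MBFRConfig()
    mre, dists = compute_mre(source.transformed(fitted), target)
    loo = None
    if cfg.leave_one_out and len(source) > 3:
        loo_d = []
        for i, label in enumerate(source.labels):
            keep = [l for l in source.labels if l != label]
            t_i = kabsch_fit(source.reordered(keep), target.reordered(keep))
            loo_d.append(np.linalg.norm(
                t_i.apply(source.coords[i]) - target.get(label)))
        loo = float(np.sqrt(np.mean(np.square(loo_d))))
    return RegistrationResult(
        transform=fitted,
        per_marker_distance=dists,
        mre=mre,
        n_markers=len(source),
        status=_status(mre, cfg.failure_threshold_mm),
        method=method,
        marker_labels=tuple(source.labels),
        mre_leave_one_out=loo,
    )


def run_mbfr(ct: Volume, mr: Volume, cfg: Optional[MBFRConfig] = None) -> RegistrationResult:
    """Full MBFR pipeline registering *ct* into the world of *mr*.

    Stage failures are re-raised as :class:`RegistrationStageError` with the
    stage name (``detect-ct``, ``detect-mr``, ``match``, ``fit``).
    """
    cfg = cfg or MBFRConfig()

    def cap(ms: MarkerSet) -> MarkerSet:
        # under noise, speckle can pass the size window; spurious components
        # are smaller than true markers and get dropped here (the distance
        # matcher would also reject them, but this keeps it fast)
        if len(ms) <= cfg.max_detections:
            return ms
        keep = sorted(ms.markers, key=lambda m: m.voxel_count,
                      reverse=True)[: cfg.max_detections]
        return MarkerSet(keep, ms.modality)

    try:
        lo, hi = cfg.voxel_window(ct)
        ct_set = cap(detect_markers(ct, cfg.ct_marker_threshold, lo, hi))
        if len(ct_set) < 3:
            raise MarmoregError(f"only {len(ct_set)} markers detected in CT")
    except MarmoregError as exc:
        raise RegistrationStageError("detect-ct", exc) from exc

    try:
        mr_threshold = float(np.percentile(mr.data, cfg.mr_marker_percentile))
        lo, hi = cfg.voxel_window(mr)
        mr_set = cap(detect_markers(mr, mr_threshold, lo, hi))
        if len(mr_set) < 3:
            raise MarmoregError(f"only {len(mr_set)} markers detected in MR")
    except MarmoregError as exc:
        raise RegistrationStageError("detect-mr", exc) from exc

    try:
        corr = match_markers(ct_set, mr_set, tol=cfg.match_tol_mm)
    except MarmoregError as exc:
        raise RegistrationStageError("match", exc) from exc

    source = ct_set.to_pointset(corr.labels_a())
    # relabel MR points with the CT labels so the fit sees matched names
    target = PointSet(corr.labels_a(),
                      np.array([mr_set.get(lb).centroid for lb in corr.labels_b()]))
    try:
        fitted = kabsch_fit(source, target)
    except (DegenerateGeometryError, InputError) as exc:
        raise RegistrationStageError("fit", exc) from exc

    return result_from_points(fitted, source, target, cfg)


def summarize_cohort(results: Sequence[RegistrationResult]) -> CohortSummary:
    """Failure probability and MRE statistics over a cohort of registrations."""
    results = list(results)
    if not results:
        raise InputError("summarize_cohort of an empty list")
    mres = np.array([r.mre for r in results], dtype=float)
    failed = np.array([r.status is RegistrationStatus.FAILED for r in results])
    ok = mres[~failed]
    return CohortSummary(
        n_total=len(results),
        n_failed=int(failed.sum()),
        failure_probability=float(failed.sum()) / len(results),
        mre_mean=float(mres.mean()),
        mre_sd=float(mres.std(ddof=1)) if len(mres) > 1 else 0.0,
        mre_mean_ok=float(ok.mean()) if len(ok) else None,
        mre_sd_ok=float(ok.std(ddof=1)) if len(ok) > 1 else (0.0 if len(ok) else None),
    )
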