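"""Fiducial marker detection, quality control and cross-modal correspondence.

Markers are detected as 26-connected components of a thresholded volume,
filtered by a voxel-count window sized from the physical marker cavity.
Correspondence between modalities is established purely from inter-marker
distance-matrix consistency (rigid motions preserve pairwise distances), so
no initial transform is needed.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import AmbiguousMatchError, DegenerateGeometryError, InputError, MatchingError
from .geometry import PointSet, _collinearity_ratio
from .volumes_io import Modality, Volume

__all__ = ["Marker", "MarkerSet", "Correspondence", "detect_markers", "match_markers"]

#: default asymmetry above which a marker is suspected of containing a bubble
ASYMMETRY_FLAG_DEFAULT = 0.15

#: relative extent (2nd/1st singular value) below which a constellation is
#: treated as near-collinear: too ill-conditioned for a rigid fit
COLLINEAR_RATIO = 1e-3


@dataclass(frozen=True)
class Marker:
    label: str
    centroid: np.ndarray           # world mm
    voxel_count: int
    bounding_size: float           # longest bounding-box edge, mm
    asymmetry: float               # 1 - self-overlap under point reflection, in [0, 1]
    touches_border: bool = False

    def flagged(self, threshold: float = ASYMMETRY_FLAG_DEFAULT) -> bool:
        return self.touches_border or self.asymmetry > threshold


@dataclass
class MarkerSet:
    markers: list
    modality: Modality

    def __post_init__(self):
        labels = [m.label for m in self.markers]
        if len(set(labels)) != len(labels):
            raise InputError("marker labels must be unique")
        for m in self.markers:
            if m.voxel_count <= 0:
                raise InputError(f"marker {m.label} has no voxels")

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def labels(self) -> list:
        return [m.label for m in self.markers]

    @property
    def centroids(self) -> np.ndarray:
        return np.array([m.centroid for m in self.markers]).reshape(len(self), 3)

    def to_pointset(self, labels: Optional[Sequence] = None) -> PointSet:
        if labels is None:
            return PointSet(self.labels, self.centroids)
        coords = [m.centroid for m in self.markers if m.label in set(labels)]
        return PointSet(list(labels), np.array(coords))

    def get(self, label) -> Marker:
        for m in self.markers:
            if m.label == label:
                return m
        raise KeyError(label)

    # -- serialisation --------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "label": m.label,
                "x": m.centroid[0], "y": m.centroid[1], "z": m.centroid[2],
                "voxels": m.voxel_count,
                "bounding_size_mm": m.bounding_size,
                "asymmetry": m.asymmetry,
                "touches_border": m.touches_border,
            }
            for m in self.markers
        ]
        return pd.DataFrame(rows, columns=["label", "x", "y", "z", "voxels",
                                           "bounding_size_mm", "asymmetry",
                                           "touches_border"])

    def to_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"modality": self.modality.value,
             "markers": self.to_dataframe().to_dict(orient="records")}, indent=2))

    @classmethod
    def from_tsv(cls, path, modality: "Modality | str" = Modality.CT) -> "MarkerSet":
        df = pd.read_csv(path, sep="\t")
        markers = [
            Marker(str(r.label), np.array([r.x, r.y, r.z]), int(r.voxels),
                   float(getattr(r, "bounding_size_mm", 0.0)),
                   float(getattr(r, "asymmetry", 0.0)),
                   bool(getattr(r, "touches_border", False)))
            for r in df.itertuples()
        ]
        return cls(markers, Modality(modality))


@dataclass(frozen=True)
class Correspondence:
    pairs: tuple                    # ((label_a, label_b), ...)
    rms_distance_residual: float    # rms of |D_a - D_b| over matched pairs, mm

    def __post_init__(self):
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise InputError("correspondence must be a partial bijection")

    def __len__(self) -> int:
        return len(self.pairs)

    def labels_a(self) -> list:
        return [p[0] for p in self.pairs]

    def labels_b(self) -> list:
        return [p[1] for p in self.pairs]


def detect_markers(
    v: Volume,
    threshold: float,
    min_voxels: int = 1,
    max_voxels: int = np.iinfo(np.int64).max,
    intensity_weighted: bool = False,
) -> MarkerSet:
    """Detect fiducial markers as 26-connected supra-threshold components.

    Components are kept when their voxel count lies in
    ``[min_voxels, max_voxels]``.  The centroid is the unweighted mean of
    the component voxel world-centres (binary centroid); pass
    ``intensity_weighted=True`` for an intensity-weighted variant.
    Components touching the volume border are flagged.  The asymmetry score
    is ``1 - overlap(component, its point reflection about the centroid) /
    voxel_count``: 0 for perfectly symmetric shapes, rising when e.g. an
    air bubble eats one end of the marker cavity.
    """
    mask = v.data >= threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labelled, n = ndimage.label(mask, structure=structure)
    if n == 0:
        warnings.warn("no supra-threshold components found; empty MarkerSet")
        return MarkerSet([], v.modality)

    counts = np.bincount(labelled.ravel())
    markers = []
    voxset_cache = {}
    for comp in range(1, n + 1):
        count = int(counts[comp])
        if not (min_voxels <= count <= max_voxels):
            continue
        idx = np.argwhere(labelled == comp)
        if intensity_weighted:
            w = v.data[tuple(idx.T)].astype(float)
            w = np.clip(w - threshold, 0, None) + 1e-12
            centroid_vox = (idx * w[:, None]).sum(axis=0) / w.sum()
        else:
            centroid_vox = idx.mean(axis=0)
        centroid = v.voxel_to_world(centroid_vox)
        extent_mm = (idx.max(axis=0) - idx.min(axis=0) + 1) * v.voxel_sizes
        touches = bool((idx == 0).any() or
                       (idx == np.array(v.shape) - 1).any())
        # point reflection about the (continuous) centroid, rounded to grid
        reflected = np.rint(2.0 * centroid_vox - idx).astype(int)
        voxset = set(map(tuple, idx))
        overlap = sum(tuple(r) in voxset for r in reflected)
        asymmetry = 1.0 - overlap / count
        markers.append(Marker(
            label=f"m{len(markers) + 1}",
            centroid=centroid,
            voxel_count=count,
            bounding_size=float(extent_mm.max()),
            asymmetry=float(asymmetry),
            touches_border=touches,
        ))
    return MarkerSet(markers, v.modality)


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.linalg.norm(diff, axis=2)


def match_markers(a: MarkerSet, b: MarkerSet, tol: float = 0.5) -> Correspondence:
    """Pair markers across modalities by pairwise-distance consistency.

    Searches exhaustively (n <= 8 per set) for the largest injective
    pairing whose two inter-marker distance matrices agree entrywise within
    *tol* mm, returning the one with the smallest rms distance-matrix
    residual.  Spurious detections end up unmatched.

    Raises
    ------
    MatchingError
        if no pairing of size >= 3 survives.
    AmbiguousMatchError
        if distinct pairings tie (symmetric constellations); the tied
        pairings are attached to the exception.
    DegenerateGeometryError
        if the best pairing's points are (near-)collinear.
    """
    if len(a) < 3 or len(b) < 3:
        raise MatchingError(f"need >= 3 markers per set, got {len(a)} and {len(b)}")
    if len(a) > 40 or len(b) > 40:
        raise InputError("marker matching supports at most 40 markers per set")
    if len(a) > 8 or len(b) > 8:
        return _match_markers_seeded(a, b, tol)

    ca, cb = a.centroids, b.centroids
    da, db = _distance_matrix(ca), _distance_matrix(cb)
    na, nb = len(a), len(b)

    best = None  # (rms, a_idx, b_idx)
    ties = []
    for k in range(min(na, nb), 2, -1):
        for a_idx in itertools.combinations(range(na), k):
            sub_a = da[np.ix_(a_idx, a_idx)]
            for b_idx in itertools.permutations(range(nb), k):
                sub_b = db[np.ix_(b_idx, b_idx)]
                dev = np.abs(sub_a - sub_b)
                if dev.max() > tol:
                    continue
                iu = np.triu_indices(k, 1)
                rms = float(np.sqrt((dev[iu] ** 2).mean()))
                cand = (rms, a_idx, b_idx)
                if best is None or rms < best[0] - 1e-9:
                    best = cand
                    ties = [cand]
                elif abs(rms - best[0]) <= 1e-9 and (a_idx, b_idx) != (best[1], best[2]):
                    ties.append(cand)
        if best is not None:
            break  # a maximal pairing exists at this size

    if best is None:
        raise MatchingError(f"no distance-consistent pairing of size >= 3 within tol={tol} mm")

    rms, a_idx, b_idx = best
    if _collinearity_ratio(ca[list(a_idx)]) < COLLINEAR_RATIO:
        raise DegenerateGeometryError("matched markers are (near-)collinear")
    if len(ties) > 1:
        pairings = [
            tuple((a.labels[i], b.labels[j]) for i, j in zip(ai, bi))
            for _, ai, bi in ties
        ]
        raise AmbiguousMatchError(
            f"{len(ties)} pairings tie at rms residual {rms:.3g} mm", pairings)

    pairs = tuple((a.labels[i], b.labels[j]) for i, j in zip(a_idx, b_idx))
    return Correspondence(pairs, rms)


def _match_markers_seeded(a: MarkerSet, b: MarkerSet, tol: float) -> Correspondence:
    """Triplet-seeded greedy matching for sets too large for brute force.

    Every distance-consistent triangle pair seeds a candidate pairing that
    is greedily extended with markers whose distances to all already-matched
    markers agree within *tol*; the largest pairing (ties broken by rms
    residual) wins.  Spurious detections have arbitrary distances and are
    left unmatched.
    """
    ca, cb = a.centroids, b.centroids
    da, db = _distance_matrix(ca), _distance_matrix(cb)
    na, nb = len(a), len(b)

    # hash b-triangles by their tol-quantized sorted side lengths so each
    # a-triangle only probes a handful of candidates
    bhash: dict = {}
    for b_tri in itertools.combinations(range(nb), 3):
        sides = sorted((db[b_tri[0], b_tri[1]], db[b_tri[0], b_tri[2]],
                        db[b_tri[1], b_tri[2]]))
        key = tuple(int(np.floor(s / tol)) for s in sides)
        bhash.setdefault(key, []).append(b_tri)

    best = None  # (-size, rms, a_idx tuple, b_idx tuple)
    neighbours = list(itertools.product((-1, 0, 1), repeat=3))
    for a_tri in itertools.combinations(range(na), 3):
        sub_a = da[np.ix_(a_tri, a_tri)]
        if _collinearity_ratio(ca[list(a_tri)]) < COLLINEAR_RATIO:
            continue
        sides_a = sorted((sub_a[0, 1], sub_a[0, 2], sub_a[1, 2]))
        key_a = tuple(int(np.floor(s / tol)) for s in sides_a)
        candidates = []
        for off in neighbours:
            candidates.extend(bhash.get(
                (key_a[0] + off[0], key_a[1] + off[1], key_a[2] + off[2]), []))
        seeds = []
        for b_combo in candidates:
            for b_tri in itertools.permutations(b_combo):
                sub_b = db[np.ix_(b_tri, b_tri)]
                if np.abs(sub_a - sub_b).max() <= tol:
                    seeds.append(b_tri)
        for b_tri in seeds:
            matched_a, matched_b = list(a_tri), list(b_tri)
            for i in range(na):
                if i in matched_a:
                    continue
                dists_a = da[i, matched_a]
                candidates = [
                    j for j in range(nb) if j not in matched_b
                    and np.abs(db[j, matched_b] - dists_a).max() <= tol
                ]
                if len(candidates) == 1:
                    matched_a.append(i)
                    matched_b.append(candidates[0])
                elif len(candidates) > 1:
                    devs = [np.abs(db[j, matched_b] - dists_a).max() for j in candidates]
                    matched_a.append(i)
                    matched_b.append(candidates[int(np.argmin(devs))])
            k = len(matched_a)
            dev = da[np.ix_(matched_a, matched_a)] - db[np.ix_(matched_b, matched_b)]
            iu = np.triu_indices(k, 1)
            rms = float(np.sqrt((dev[iu] ** 2).mean()))
            cand = (-k, rms, tuple(matched_a), tuple(matched_b))
            if best is None or cand[:2] < best[:2]:
                best = cand
        if best is not None and -best[0] == min(na, nb) and best[1] <= tol / 10:
            break  # complete, tight pairing: good enough
    if best is None or -best[0] < 3:
        raise MatchingError(f"no distance-consistent pairing of size >= 3 within tol={tol} mm")
    _, rms, a_idx, b_idx = best
    if _collinearity_ratio(ca[list(a_idx)]) < COLLINEAR_RATIO:
        raise DegenerateGeometryError("matched markers are (near-)collinear")
    pairs = tuple((a.labels[i], b.labels[j]) for i, j in zip(a_idx, b_idx))
    return Correspondence(pairs, rms)
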