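"""Synthetic head phantom generator for CT/MR registration testing.

The phantom is an ellipsoidal head: a brain compartment inside a
bone-density cranial shell, a thin soft-tissue scalp outside it, air
beyond, and >= 6 cylindrical dual-modality fiducial markers held on a
virtual holder around the head (container 3.2 mm dia x 3.55 mm long,
liquid cavity 2.0 mm dia x 2.0 mm).  Shapes are rasterized analytically
with per-axis supersampling so centroid ground truth is sub-voxel
accurate.  Every generator is deterministic given the spec seed and emits
its ground truth (true transforms, marker centroids, landmarks) alongside
the images.

The scene is defined in the MR scanner world; the CT volume is rendered in
its own world related to the scene by the spec's ``true_ct_to_mr``
transform, so registering CT to MR should recover exactly that transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np

from .errors import PhantomSpecError
from .frames import FrameName, LandmarkSet, fit_acpc_frame, fit_stereotactic_frame
from .geometry import PointSet, RigidTransform, euler_compose
from .repro_stats import RepeatedMeasures
from .volumes_io import LabelMask, Modality, Volume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "generate_phantom",
    "simulate_positionings",
    "simulate_cohort_landmarks",
    "POSITIONING_PARAMETERS",
]

# tissue labels
AIR, SOFT, BONE, BRAIN, PLASTIC, LIQUID = 0, 1, 2, 3, 4, 5

#: plausible tissue intensities; only their ordering/contrast matters
DEFAULT_INTENSITIES = {
    "CT":  {AIR: -1000.0, SOFT: 40.0, BONE: 1500.0, BRAIN: 40.0, PLASTIC: 120.0, LIQUID: 1200.0},
    # cortical bone is signal-void in T2w (same as air): boundary-contrast
    # refinement then sees positive contrast at bone/tissue interfaces and a
    # neutral (not repulsive) bone/air interface
    "T2w": {AIR: 0.0, SOFT: 400.0, BONE: 0.0, BRAIN: 500.0, PLASTIC: 20.0, LIQUID: 1000.0},
    "T1w": {AIR: 0.0, SOFT: 350.0, BONE: 100.0, BRAIN: 600.0, PLASTIC: 20.0, LIQUID: 300.0},
}

# six asymmetric holder directions (unit-ish, normalised at use); chosen so
# no marker subset is close to collinear and the constellation has no
# nontrivial symmetry, which keeps distance-matrix matching unambiguous
DEFAULT_MARKER_DIRECTIONS = np.array([
    [0.90, 0.25, 0.35],
    [-0.80, 0.45, 0.30],
    [0.15, 0.95, 0.45],
    [-0.25, -0.90, 0.40],
    [0.70, -0.60, 0.55],
    [-0.55, 0.10, 0.90],
])

POSITIONING_PARAMETERS = ("pitch_deg", "roll_deg", "yaw_deg", "tx_mm", "ty_mm", "tz_mm")


@dataclass
class PhantomSpec:
    head_semiaxes: tuple = (25.0, 20.0, 18.0)   # mm
    shell_thickness: float = 1.0                # mm
    scalp_thickness: float = 1.5                # mm
    ct_voxel: float = 0.24                      # mm isotropic (desk scale)
    mr_voxel: float = 0.48                      # mm isotropic (desk scale)
    marker_directions: np.ndarray = field(
        default_factory=lambda: DEFAULT_MARKER_DIRECTIONS.copy())
    marker_clearance: float = 2.5               # holder stand-off from scalp, mm
    marker_outer: tuple = (3.2, 3.55)           # container diameter, length (mm)
    marker_inner: tuple = (2.0, 2.0)            # cavity diameter, length (mm)
    bubble_fraction: tuple = ()                 # per-marker fraction of cavity in [0, 1)
    noise_sd: Dict[str, float] = field(default_factory=lambda: {"CT": 0.0, "MR": 0.0})
    #: Gaussian point-spread (sigma, mm) applied to the MR channels after
    #: rasterization.  Grades tissue boundaries over ~2 sigma, as a real
    #: scanner PSF does; without it boundary-contrast costs sit on a flat
    #: saturated plateau around the optimum.
    mr_psf_mm: float = 0.5
    intensities: Dict[str, Dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTENSITIES.items()})
    true_ct_to_mr: RigidTransform = field(default_factory=RigidTransform.identity)
    # bony protuberances on the outer shell: (direction, radius as a fraction
    # of the smallest semiaxis).  They break the near-rotational symmetry of
    # the ellipsoid so boundary-based refinement can pin down rotations.
    skull_bumps: tuple = (
        ((0.00, -0.95, 0.31), 0.28),
        ((0.80, 0.30, -0.52), 0.24),
        ((-0.30, 0.70, 0.65), 0.20),
        ((-0.85, -0.30, 0.40), 0.22),
    )
    # off-centre bone-shelled snout lobe (centre and semiaxes as fractions of
    # the head semiaxes; None disables).  Being far from the head centre it
    # converts small rotations into boundary-normal motion, which is what
    # lets boundary-based refinement constrain rotations.
    snout_centre_frac: Optional[tuple] = (0.20, 0.85, -0.25)
    snout_semiaxes_frac: tuple = (0.45, 0.50, 0.40)
    # the snout shell is thicker than the cranial one so that boundary
    # samples taken just inside its outer surface stay within bone even
    # after partial-volume blurring (a thin bright-cored shell in air would
    # repel the boundary cost)
    snout_shell_mm: float = 2.2
    stereo_pitch_deg: float = 10.0              # frontal-downward tilt of the frame
    #: amplitude of the cubic angular modulation of the head surface radius
    #: (aspheric cranium; 0 restores a pure ellipsoid)
    asphericity: float = 0.35
    supersample: int = 2
    margin: float = 1.5                         # air margin around everything, mm
    seed: int = 0

    def __post_init__(self):
        self.head_semiaxes = tuple(float(a) for a in self.head_semiaxes)
        if min(self.head_semiaxes) <= 0 or self.ct_voxel <= 0 or self.mr_voxel <= 0:
            raise PhantomSpecError("semiaxes and voxel sizes must be positive")
        dirs = np.asarray(self.marker_directions, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3 or len(dirs) < 3:
            raise PhantomSpecError("need >= 3 marker directions (n x 3)")
        norms = np.linalg.norm(dirs, axis=1)
        if (norms < 1e-9).any():
            raise PhantomSpecError("marker directions must be non-zero")
        self.marker_directions = dirs / norms[:, None]
        centres = self.marker_centres()
        s = np.linalg.svd(centres - centres.mean(axis=0), compute_uv=False)
        if s[1] / s[0] < 1e-6:
            raise PhantomSpecError("marker centres are collinear")
        bubbles = np.zeros(len(dirs)) if len(self.bubble_fraction) == 0 else np.asarray(
            self.bubble_fraction, dtype=float)
        if len(bubbles) != len(dirs):
            raise PhantomSpecError("bubble_fraction must have one entry per marker")
        if (bubbles < 0).any() or (bubbles >= 1).any():
            raise PhantomSpecError("bubble fractions must lie in [0, 1)")
        self.bubble_fraction = tuple(bubbles)
        if self.supersample < 1:
            raise PhantomSpecError("supersample must be >= 1")
        # a marker tip inside the bone shell would corrupt the shell rendering
        outer_r = np.array(self.head_semiaxes)
        for c in centres:
            if np.sum((c / outer_r) ** 2) <= 1.0:
                raise PhantomSpecError(
                    f"marker at {np.round(c, 2)} overlaps the cranial interior")
            if self.snout_centre_frac is not None:
                sc = np.asarray(self.snout_centre_frac) * outer_r
                ss = (np.asarray(self.snout_semiaxes_frac) * outer_r
                      + self.scalp_thickness)
                if np.sum(((c - sc) / ss) ** 2) <= 1.2:
                    raise PhantomSpecError(
                        f"marker at {np.round(c, 2)} overlaps the snout lobe")

    # -- derived geometry ------------------------------------------------
    def _radius_along(self, semiaxes, direction: np.ndarray) -> float:
        return 1.0 / np.sqrt(np.sum((direction / np.asarray(semiaxes)) ** 2))

    def holder_semiaxes(self) -> np.ndarray:
        return np.asarray(self.head_semiaxes) + self.scalp_thickness

    def marker_centres(self) -> np.ndarray:
        """Container centres in scene (MR world) coordinates."""
        half_len = self.marker_outer[1] / 2.0
        centres = []
        for d in self.marker_directions:
            r = self._radius_along(self.holder_semiaxes(), d)
            centres.append(d * (r + self.marker_clearance + half_len))
        return np.array(centres)

    def marker_labels(self) -> list:
        return [f"M{i + 1}" for i in range(len(self.marker_directions))]

    def true_landmarks(self) -> LandmarkSet:
        """Ground-truth landmark positions in scene coordinates.

        AC/PC lie on the scene Y axis (so the true AC-PC frame is a pure
        translation), and the stereotactic defining landmarks are placed by
        pulling canonical stereotactic-frame positions back through the
        true scanner-to-stereotactic transform.
        """
        ax, ay, az = self.head_semiaxes
        s = self.true_scanner_to_stereo()
        inv = s.inverse()
        canonical = {
            "ear_canal_L": np.array([-0.64 * ax, 0.0, 0.0]),
            "ear_canal_R": np.array([0.64 * ax, 0.0, 0.0]),
            "infraorbital_L": np.array([-0.32 * ax, 0.70 * ay, 0.0]),
            "infraorbital_R": np.array([0.32 * ax, 0.70 * ay, 0.0]),
            "bregma": np.array([0.0, 0.25 * ay, 0.95 * az]),
            "inion": np.array([0.0, -0.92 * ay, 0.30 * az]),
            "rhinion": np.array([0.0, 0.97 * ay, 0.10 * az]),
            "zygion_L": np.array([-0.92 * ax, 0.25 * ay, 0.0]),
            "zygion_R": np.array([0.92 * ax, 0.25 * ay, 0.0]),
        }
        points = {name: inv.apply(p) for name, p in canonical.items()}
        points["AC"] = np.array([0.0, 0.14 * ay, 0.0])
        points["PC"] = np.array([0.0, -0.16 * ay, 0.0])
        points["midline_superior"] = np.array([0.0, 0.0, 0.5 * az])
        return LandmarkSet(points)

    def true_scanner_to_stereo(self) -> RigidTransform:
        """Scene world -> stereotactic frame.  A frontal-downward tilt of
        the stereotactic horizontal plane corresponds to a negative X
        rotation of this mapping (see frames module sign note)."""
        ay, az = self.head_semiaxes[1], self.head_semiaxes[2]
        origin = np.array([0.0, -0.05 * ay, -0.45 * az])  # interaural midpoint
        rotation = euler_compose((-self.stereo_pitch_deg, 0.0, 0.0))
        return RigidTransform(rotation, -rotation @ origin)

    def true_scanner_to_acpc(self) -> RigidTransform:
        lm = self.true_landmarks()
        frame = fit_acpc_frame(lm, PointSet(
            ["AC", "PC", "mid"], np.array([lm["AC"], lm["PC"], lm["midline_superior"]])))
        return frame.to_frame


@dataclass
class GroundTruth:
    ct_to_mr: RigidTransform
    scanner_to_acpc: RigidTransform
    scanner_to_stereo: RigidTransform
    marker_centroids_mr: PointSet       # scene world
    marker_centroids_ct: PointSet       # CT world (= ct_to_mr^-1 of the above)
    landmarks: LandmarkSet              # scene world
    labels_ct: Optional[LabelMask] = None


class _Scene:
    """Analytic tissue-label field for one phantom, queryable at any point."""

    def __init__(self, spec: PhantomSpec):
        self.spec = spec
        self.brain_semiaxes = np.asarray(spec.head_semiaxes) - spec.shell_thickness
        if min(self.brain_semiaxes) <= 0:
            raise PhantomSpecError("shell thicker than the head semiaxes")
        self.head_semiaxes = np.asarray(spec.head_semiaxes)
        self.scalp_semiaxes = self.holder = spec.holder_semiaxes()
        self.centres = spec.marker_centres()
        self.axes = spec.marker_directions
        r_out, l_out = spec.marker_outer[0] / 2.0, spec.marker_outer[1]
        r_in, l_in = spec.marker_inner[0] / 2.0, spec.marker_inner[1]
        self.r_out, self.l_out, self.r_in, self.l_in = r_out, l_out, r_in, l_in
        self.bound_sq = r_out ** 2 + (l_out / 2.0) ** 2 + 0.25
        self.snout = None
        if spec.snout_centre_frac is not None:
            centre = np.asarray(spec.snout_centre_frac) * self.head_semiaxes
            semi = np.asarray(spec.snout_semiaxes_frac) * self.head_semiaxes
            inner = semi - spec.snout_shell_mm
            if min(inner) <= 0:
                raise PhantomSpecError("snout smaller than its shell thickness")
            self.snout = (centre, semi, inner)
        self.bumps = []
        for direction, frac in spec.skull_bumps:
            d = np.asarray(direction, dtype=float)
            d = d / np.linalg.norm(d)
            centre = d * spec._radius_along(self.head_semiaxes, d)
            self.bumps.append((centre, frac * min(self.head_semiaxes)))
        cavity_volume = np.pi * r_in ** 2 * l_in
        self.bubble_radius = np.array([
            (3.0 * f * cavity_volume / (4.0 * np.pi)) ** (1.0 / 3.0) if f > 0 else 0.0
            for f in spec.bubble_fraction])

    def _shape_value(self, pts: np.ndarray, semiaxes: np.ndarray) -> np.ndarray:
        """Implicit surface function: inside where value <= 1.

        ``q * (1 + beta * g(direction))`` with q the ellipsoid quadratic form
        and g a degree-0-homogeneous cubic harmonic; homogeneous of degree 2
        in the point, so the surface crossing along a ray is analytic.
        """
        w = pts / semiaxes
        q = np.einsum("ij,ij->i", w, w)
        beta = self.spec.asphericity
        if beta == 0.0:
            return q
        with np.errstate(invalid="ignore", divide="ignore"):
            g = np.where(q > 0, w[:, 0] * w[:, 1] * w[:, 2] / np.maximum(q, 1e-30) ** 1.5, 0.0)
        return q * (1.0 + beta * g)

    def radial_distance_to_head_surface(self, pts: np.ndarray) -> np.ndarray:
        """Exact distance along each point's ray to the outer head surface."""
        f = self._shape_value(pts, self.head_semiaxes)
        r = np.linalg.norm(pts, axis=1)
        return np.abs(r * (1.0 - 1.0 / np.sqrt(np.maximum(f, 1e-30))))

    def labels(self, pts: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pts), dtype=np.uint8)
        # skin covers every bony surface (cranium, bumps and snout alike) so
        # the outer bone boundary sees soft tissue, not air
        q = self._shape_value(pts, self.scalp_semiaxes)
        soft = q <= 1.0
        t = self.spec.scalp_thickness
        if self.snout is not None:
            centre, semi, _ = self.snout
            d = pts - centre
            soft |= np.sum((d / (semi + t)) ** 2, axis=1) <= 1.0
        for centre, radius in self.bumps:
            d = pts - centre
            soft |= np.einsum("ij,ij->i", d, d) <= (radius + t) ** 2
        out[soft] = SOFT
        q = self._shape_value(pts, self.head_semiaxes)
        out[q <= 1.0] = BONE
        q_brain = self._shape_value(pts, self.brain_semiaxes)
        for centre, radius in self.bumps:
            d = pts - centre
            bump = (np.einsum("ij,ij->i", d, d) <= radius ** 2) & (q_brain > 1.0)
            out[bump] = BONE
        if self.snout is not None:
            centre, semi, inner = self.snout
            d = pts - centre
            out[np.sum((d / semi) ** 2, axis=1) <= 1.0] = BONE
            out[np.sum((d / inner) ** 2, axis=1) <= 1.0] = SOFT
        out[q_brain <= 1.0] = BRAIN

        for i, (c, u) in enumerate(zip(self.centres, self.axes)):
            d = pts - c
            close = np.einsum("ij,ij->i", d, d) <= self.bound_sq
            if not close.any():
                continue
            dc = d[close]
            axial = dc @ u
            radial_sq = np.einsum("ij,ij->i", dc, dc) - axial ** 2
            plastic = (radial_sq <= self.r_out ** 2) & (np.abs(axial) <= self.l_out / 2.0)
            cavity = (radial_sq <= self.r_in ** 2) & (np.abs(axial) <= self.l_in / 2.0)
            sub = out[close]
            sub[plastic] = PLASTIC
            sub[cavity] = LIQUID
            rb = self.bubble_radius[i]
            if rb > 0:
                bubble_centre = c + u * (self.l_in / 2.0 - rb)
                bd = pts[close] - bubble_centre
                bubble = cavity & (np.einsum("ij,ij->i", bd, bd) <= rb ** 2)
                sub[bubble] = AIR
            out[close] = sub
        return out

    def extent(self) -> float:
        """Half-width (mm) of the cube that encloses scalp and markers."""
        marker_reach = (np.linalg.norm(self.centres, axis=1)
                        + np.sqrt(self.bound_sq)).max()
        t = self.spec.scalp_thickness
        bump_reach = max((np.linalg.norm(c) + r + t for c, r in self.bumps),
                         default=0.0)
        snout_reach = 0.0
        if self.snout is not None:
            snout_reach = np.linalg.norm(self.snout[0]) + self.snout[1].max() + t
        return max(self.scalp_semiaxes.max(), marker_reach, bump_reach,
                   snout_reach) + self.spec.margin


def _centred_affine(n: np.ndarray, voxel: float, centre_world: np.ndarray) -> np.ndarray:
    affine = np.diag([voxel, voxel, voxel, 1.0])
    affine[:3, 3] = centre_world - voxel * (n - 1) / 2.0
    return affine


def _rasterize(
    scene: _Scene,
    shape: tuple,
    affine: np.ndarray,
    intensity_maps: Sequence[Dict[int, float]],
    world_to_scene: RigidTransform,
    supersample: int,
) -> list:
    """Render one or more intensity channels from a single labelling pass."""
    luts = []
    for intensities in intensity_maps:
        lut = np.zeros(max(intensities) + 1)
        for lab, val in intensities.items():
            lut[lab] = val
        luts.append(lut)
    s = supersample
    offsets = (np.arange(s) + 0.5) / s - 0.5
    m = world_to_scene.as_matrix() @ affine      # voxel index -> scene point
    lin, shift = m[:3, :3], m[:3, 3]

    outs = [np.zeros(shape, dtype=float) for _ in luts]
    jk = np.indices(shape[1:], dtype=float).reshape(2, -1)   # (2, ny*nz)
    chunk = max(1, int(2e6 // (jk.shape[1] or 1)))
    for i0 in range(0, shape[0], chunk):
        i1 = min(shape[0], i0 + chunk)
        ii = np.arange(i0, i1, dtype=float)
        # base voxel indices for this slab, shape (3, nslab*ny*nz)
        idx = np.empty((3, (i1 - i0) * jk.shape[1]))
        idx[0] = np.repeat(ii, jk.shape[1])
        idx[1] = np.tile(jk[0], i1 - i0)
        idx[2] = np.tile(jk[1], i1 - i0)
        accs = [np.zeros(idx.shape[1]) for _ in luts]
        for di in offsets:
            for dj in offsets:
                for dk in offsets:
                    sub = idx + np.array([[di], [dj], [dk]])
                    labels = scene.labels((lin @ sub).T + shift)
                    for acc, lut in zip(accs, luts):
                        acc += lut[labels]
        for out, acc in zip(outs, accs):
            out[i0:i1] = (acc / s ** 3).reshape(i1 - i0, *shape[1:])
    return outs


def generate_phantom(spec: PhantomSpec, with_labels: bool = False):
    """Render the phantom.  Returns ``(ct, t1w, t2w, truth)``.

    CT is rendered on its own grid in CT world (related to the scene by
    ``spec.true_ct_to_mr``), T1w/T2w on a shared MR grid in scene world.
    Additive Gaussian noise (``spec.noise_sd['CT'|'MR']``) is applied after
    rasterization, deterministically from ``spec.seed``.
    """
    scene = _Scene(spec)
    half = scene.extent()
    rng = np.random.default_rng(spec.seed)

    # MR grid: centred on the scene origin
    n_mr = np.ceil(2 * half / spec.mr_voxel).astype(int) * np.ones(3, dtype=int)
    mr_affine = _centred_affine(n_mr, spec.mr_voxel, np.zeros(3))
    mr_shape = tuple(n_mr)
    t2_data, t1_data = _rasterize(
        scene, mr_shape, mr_affine,
        [spec.intensities["T2w"], spec.intensities["T1w"]],
        RigidTransform.identity(), spec.supersample)
    if spec.mr_psf_mm > 0:
        from scipy import ndimage

        sigma_vox = spec.mr_psf_mm / spec.mr_voxel
        t2_data = ndimage.gaussian_filter(t2_data, sigma_vox)
        t1_data = ndimage.gaussian_filter(t1_data, sigma_vox)

    # CT grid: centred on the scene origin pulled back into CT world
    t = spec.true_ct_to_mr
    n_ct = np.ceil(2 * half / spec.ct_voxel).astype(int) * np.ones(3, dtype=int)
    ct_affine = _centred_affine(n_ct, spec.ct_voxel, t.inverse().apply(np.zeros(3)))
    ct_shape = tuple(n_ct)
    (ct_data,) = _rasterize(scene, ct_shape, ct_affine, [spec.intensities["CT"]],
                            t, spec.supersample)

    sd_ct = spec.noise_sd.get("CT", 0.0)
    sd_mr = spec.noise_sd.get("MR", 0.0)
    if sd_ct > 0:
        ct_data = ct_data + rng.normal(0.0, sd_ct, ct_data.shape)
    if sd_mr > 0:
        t1_data = t1_data + rng.normal(0.0, sd_mr, t1_data.shape)
        t2_data = t2_data + rng.normal(0.0, sd_mr, t2_data.shape)

    labels_ct = None
    if with_labels:
        (lab,) = _rasterize(scene, ct_shape, ct_affine,
                            [{k: float(k) for k in range(6)}], t, 1)
        labels_ct = LabelMask(np.rint(lab).astype(np.uint8), ct_affine)

    marker_labels = spec.marker_labels()
    centres_mr = PointSet(marker_labels, scene.centres)
    truth = GroundTruth(
        ct_to_mr=t,
        scanner_to_acpc=spec.true_scanner_to_acpc(),
        scanner_to_stereo=spec.true_scanner_to_stereo(),
        marker_centroids_mr=centres_mr,
        marker_centroids_ct=centres_mr.transformed(t.inverse()),
        landmarks=spec.true_landmarks(),
        labels_ct=labels_ct,
    )
    ct = Volume(ct_data, ct_affine, Modality.CT)
    t1w = Volume(t1_data, mr_affine, Modality.T1w)
    t2w = Volume(t2_data, mr_affine, Modality.T2w)
    return ct, t1w, t2w, truth


def simulate_positionings(
    n_subjects: int,
    n_reps: int,
    bias: Sequence[float],
    within_sd: Sequence[float],
    between_sd: Sequence[float],
    seed: int = 0,
):
    """Simulate repeated stereotactic mountings.

    Each of the six pose parameters (pitch/roll/yaw in degrees, x/y/z
    translation in mm) is drawn as ``bias + subject_effect + rep_noise``
    with Gaussian subject effects (*between_sd*) and repetition noise
    (*within_sd*).  Returns ``(tables, truth)`` where *tables* maps the
    parameter name to a :class:`RepeatedMeasures` and *truth* records the
    generating values.
    """
    bias = np.asarray(bias, dtype=float).reshape(6)
    within = np.asarray(within_sd, dtype=float).reshape(6)
    between = np.asarray(between_sd, dtype=float).reshape(6)
    if (within < 0).any() or (between < 0).any():
        raise PhantomSpecError("standard deviations must be non-negative")
    rng = np.random.default_rng(seed)
    tables = {}
    for p, name in enumerate(POSITIONING_PARAMETERS):
        subject = rng.normal(0.0, between[p], size=(n_subjects, 1)) if between[p] > 0 \
            else np.zeros((n_subjects, 1))
        noise = rng.normal(0.0, within[p], size=(n_subjects, n_reps)) if within[p] > 0 \
            else np.zeros((n_subjects, n_reps))
        values = bias[p] + subject + noise
        units = "deg" if name.endswith("deg") else "mm"
        tables[name] = RepeatedMeasures(values, parameter=name, units=units)
    denom = between ** 2 + within ** 2
    pop_icc = np.divide(between ** 2, denom, out=np.zeros(6), where=denom > 0)
    truth = {"bias": bias, "within_sd": within, "between_sd": between,
             "population_icc": pop_icc}
    return tables, truth


def simulate_cohort_landmarks(
    n: int,
    true_landmarks: LandmarkSet,
    per_landmark_sd,
    seed: int = 0,
    presence_probability: Optional[Dict[str, float]] = None,
):
    """Draw a cohort of landmark sets with Gaussian per-axis scatter.

    *per_landmark_sd* is a scalar, a 3-vector, or a dict mapping landmark
    name to either.  *presence_probability* optionally drops a landmark
    from some subjects (emulating anatomy visible only in a subset).
    Returns ``(cohort, drawn_counts)``.
    """
    if n < 1:
        raise PhantomSpecError("cohort size must be positive")
    rng = np.random.default_rng(seed)
    presence_probability = presence_probability or {}

    def sd_for(name) -> np.ndarray:
        sd = per_landmark_sd
        if isinstance(sd, dict):
            sd = sd.get(name, 0.0)
        return np.broadcast_to(np.asarray(sd, dtype=float), (3,))

    cohort = []
    counts = {name: 0 for name in true_landmarks.names}
    for _ in range(n):
        points = {}
        for name in true_landmarks.names:
            if rng.random() >= presence_probability.get(name, 1.0):
                continue
            points[name] = true_landmarks[name] + rng.normal(0.0, 1.0, 3) * sd_for(name)
            counts[name] += 1
        cohort.append(LandmarkSet(points))
    return cohort, counts
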