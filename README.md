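# marmoreg

Multimodal CT–MR brain-targeting toolkit for small-animal imaging:
marker-based fiducial registration (MBFR) with a registration-error metric
and failure rule, boundary-contrast ("BBR-style") refinement, AC-PC and
image-based stereotactic coordinate frames with frame-bias decomposition,
reproducibility statistics (ICC(1,1), exact Wilcoxon signed-rank,
coefficients of variation, isometric scale ratios), and a fully synthetic
digital head phantom so every stage is testable without any real scan.

## Layout

| module | role |
| --- | --- |
| `marmoreg.geometry` | rigid transforms, Euler decomposition, Kabsch fitting, transform averaging/de-drifting, point-to-line distances |
| `marmoreg.volumes_io` | `Volume` model, NIfTI-1 I/O, thresholding, rigid resampling |
| `marmoreg.markers` | fiducial detection (connected components + QC) and cross-modal correspondence from pairwise distances |
| `marmoreg.mbfr` | the MBFR pipeline, MRE metric, failure rule, cohort summaries |
| `marmoreg.bbr_refine` | bone-boundary extraction and tanh boundary-contrast refinement |
| `marmoreg.frames` | AC-PC / stereotactic frame construction and frame bias |
| `marmoreg.repro_stats` | ICC(1,1) with F-based CI, exact Wilcoxon, COV, variability tables |
| `marmoreg.phantom` | seed-deterministic CT/T1w/T2w phantom generator with ground truth, plus repeated-positioning and cohort simulators |

## Conventions

* World coordinates are right-handed RAS millimetres.
* Euler angles are fixed-axis (extrinsic) X-then-Y-then-Z (`R = Rz@Ry@Rx`),
  reported in degrees: pitch about X, roll about Y, yaw about Z.
* Transform files are plain-text 4×4 row-major world-mm matrices
  (last row `0 0 0 1`); `.json` files carry the rotation matrix,
  translation, and Euler angles with the convention string.
* CT volumes are in Hounsfield units (air −1000, water 0); a registration
  is reported `failed` when the marker registration error exceeds 1 mm.

## CLI

```sh
# synthetic phantom pair with ground truth (use --paper-resolution for
# 0.12 mm CT / 0.36 mm MR rendering)
marmoreg phantom --out demo/ --seed 1

# fiducial detection
marmoreg detect-markers --volume demo/ct.nii.gz --modality CT \
    --threshold 800 --min-voxels 50 --max-voxels 900 --out markers.tsv

# marker-based registration (exit code 1 if the MRE fails the 1 mm rule)
marmoreg register --fixed demo/t2w.nii.gz --moving demo/ct.nii.gz \
    --out xfm.mat --report result.json

# boundary-contrast fine-tuning of an initial transform
marmoreg refine --init xfm.mat --ct demo/ct.nii.gz --mr demo/t2w.nii.gz \
    --out xfm_refined.mat

# coordinate frames and their bias from a landmark table (name,x,y,z CSV)
marmoreg frames --landmarks demo/landmarks.csv --bias

# reproducibility of a subjects x repetitions table
marmoreg icc --table reps.tsv

# per-landmark cohort variability
marmoreg variability --landmarks subj1.csv --landmarks subj2.csv
```

## Notes

* `refine_bbr` assumes its initial transform is within ~2 mm / 5° of the
  optimum (e.g. an MBFR result); larger corrections are flagged as basin
  escapes. The default cost slope is −0.5; on noiseless synthetic phantoms
  a gentler slope (e.g. −0.05) keeps the per-point tanh out of saturation
  and is what the accuracy tests use.
* The phantom renders at desk-scale voxel sizes by default
  (0.24 mm CT / 0.48 mm MR); all geometry scales continuously.
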