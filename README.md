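# fluorotrack

Automatic anatomical-landmark detection and tracking for single-plane
shoulder fluoroscopy.

Assessing shoulder kinematics — for example in patients with rotator
cuff tears — from pulsed fluoroscopy requires localising a handful of
anatomical landmarks in every frame of an abduction–adduction sequence:
the glenohumeral joint centre (centre of a best-fit circle on the
humeral head), the superior and inferior edges of the glenoid, the most
lateral point of the acromion, a point on the humeral-shaft axis, and a
25 mm radio-opaque calibration sphere. Manual labelling takes about a
minute per frame; `fluorotrack` implements the automatic alternative:

1. **Landmark ⇄ disc-mask codec.** Point localisation is recast as
   semantic segmentation by rasterising a filled *label disc* at each
   landmark (radius 8 px for the point landmarks, the fitted-circle
   radius for the others; a radius-8 disc at an integer centre covers
   exactly 197 pixels). Decoding keeps, per label, only the largest
   connected component of the predicted volume (26-connectivity across
   the stacked frames, or 8-connectivity per frame) and takes each
   label's per-frame centre of mass as the landmark position; absent
   labels are reported as detection failures, never imputed.
2. **Pseudo-3D stacking** of frames along the acquisition-time axis, so
   a 3D segmenter sees the temporal neighbours of each frame, plus a
   dataset exporter in the `imagesTr`/`labelsTr` NIfTI layout with a
   manifest that keeps every shoulder's sequences in one fold group.
3. **A pluggable segmentation backend**: an adapter seam for an external
   trained network, and a ground-truth oracle with a controlled
   corruption model (rigid disc jitter, per-frame label dropout, disc
   erosion) for weight-free end-to-end testing.
4. **Calibration**: the imaged sphere's area-equivalent diameter
   2·√(area/π), averaged over the sequence, gives the isotropic scale
   mm/px = 25 / d̄.
5. **Kinematics**: the abduction angle is the angle between image
   vertical and the glenohumeral-centre → shaft line,
   θ = atan2(|Δx|, Δy), mirrored in x for left shoulders.
6. **Agreement suite** for any annotation pair (automatic vs ground
   truth, intra-/inter-rater): per-label Dice 2|A∩B|/(|A|+|B|),
   per-landmark |Δx|, |Δy| and Euclidean distance summaries (px and mm,
   stratified by pulse rate), Bland–Altman limits of agreement
   d̄ ± 1.96·SD, intraclass correlation ICC(2,1) with F-based 95% CI,
   and per-stratum detection-failure tables.
7. **A synthetic phantom** rendering full-resolution sequences
   (946 × 958 px, 0.35 mm/px, 3 or 10 Hz, 0°→30°→0° raised-cosine
   abduction) with exactly known ground truth.

## Worked example

```python
import numpy as np
import fluorotrack as ft
from fluorotrack.phantom import ground_truth

cfg = ft.PhantomConfig()              # 946 x 958 px, 0.35 mm/px, 10 Hz, 30 deg task
truth = ground_truth(cfg)             # exact per-frame landmarks

# emulate a segmentation model with 2 px localisation error
labels = ft.oracle_predict(truth, cfg.image_shape,
                           ft.CorruptionSpec(jitter_sigma_px=2.0, seed=0))
filtered = ft.largest_component_filter(labels)
detected = ft.mask_to_landmarks(filtered)

cal = ft.calibrate(filtered)
print(f"recovered scale: {cal.mm_per_px:.4f} mm/px")

series = ft.kinematic_series(detected)
print(f"peak abduction: {np.nanmax(series.angles_deg):.2f} deg")

report = ft.compare_raters(detected, truth, mm_per_px=cal.mm_per_px)
row = report.distances.query("landmark == 'glenohumeral_centre' and stratum == 'all'").iloc[0]
print(f"GH centre error: {row['mean_euclidean_mm']:.2f} +/- {row['sd_euclidean_mm']:.2f} mm")
err = ft.angle_error(ft.kinematic_series(detected), ft.kinematic_series(truth))
print(f"abduction angle error: {err.mean_absolute:.2f} +/- {err.sd_absolute:.2f} deg")
```

prints

```
recovered scale: 0.3500 mm/px
peak abduction: 30.64 deg
GH centre error: 0.91 +/- 0.49 mm
abduction angle error: 0.44 +/- 0.32 deg
```

The recovered scale matches the true pixel pitch, a 2 px disc jitter
translates into sub-millimetre landmark error, and the abduction angle
— which divides the jitter by a ~10 cm lever arm — is accurate to well
under a degree.

The same workflow is available from the shell, one subcommand per
stage:

```sh
fluorotrack simulate --out work
fluorotrack predict --images work/images.nii.gz --truth work/truth.json \
                    --jitter-sigma 2 --out work/pred.nii.gz
fluorotrack extract --labels work/pred.nii.gz --out-csv work/coords.csv
fluorotrack evaluate --a work/coords.csv --b work/truth.json --out work/report
# or everything at once:
fluorotrack run --out work --seed 0 --jitter-sigma 2
```

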