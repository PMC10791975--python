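# Methods

This note records the models, conventions and numerical choices behind
`fluorotrack`, and what the synthetic tests do and do not establish
about clinical data.

## Coordinate and label conventions

All modules share one convention: 0-based pixel coordinates with the
origin at the top-left pixel centre, x rightward (lateral–medial), y
downward (superior–inferior). Positions are continuous; an integer
coordinate is a pixel centre. Volumes are ordered (frame, y, x) with the
frame axis strictly sorted by (timestamp, source file name, frame
index); missing timestamps fall back to `frame_index / pulse_rate_hz`
so ordering stays total, and timestamp ties are broken by file name for
determinism.

The integer label scheme is fixed: 1 glenohumeral centre (humeral
head), 2 glenoid superior, 3 glenoid inferior, 4 acromion lateral,
5 humeral shaft, 6 reference sphere, 0 background. The source
annotations identify landmarks by colour/name only, so the constant
mapping is what keeps masks interchangeable between tools.

## Landmark ⇄ mask codec

**Encoding.** Each landmark becomes a filled disc: a pixel belongs to a
disc iff the Euclidean distance from its centre coordinate to the
landmark position is ≤ the radius (boundary inclusive — this makes the
rasterisation reproducible; a radius-8 disc at an integer centre covers
exactly 197 lattice points). The glenoid edges and the acromion use a
fixed 8 px radius; the humeral head, shaft and sphere use their
fitted-circle radius. When a shaft annotation carries no fitted circle,
the radius defaults to 8 px (configurable) — the shaft's manual circle
is not otherwise quantified, and matching the fixed-radius landmarks is
the conservative choice. Discs reaching outside the image are clipped
with a warning. Overlaps are resolved by a fixed precedence (sphere >
humeral head > shaft > acromion > glenoid superior > glenoid inferior),
larger structures being least harmed by losing a boundary pixel;
overlaps are logged.

**Post-processing.** Per label, only the largest connected component of
the predicted volume is kept. The default connectivity is 3D
(26-neighbourhood) across the stacked frames: landmarks move smoothly
between consecutive pulses, so a label's discs form a temporally
connected tube and isolated false positives in single frames are
removed. Ties in component size are broken by the component whose seed
voxel comes first in (frame, y, x) raster order. A per-frame 2D mode
(8-neighbourhood) exists behind a flag; it is the right choice when the
inter-frame motion exceeds the disc diameter (see the pulse-rate note
below) and for dropout bookkeeping, where 3D filtering would let a
missing frame split a label's track and erase its smaller half.

**Decoding.** The landmark position is the unweighted centroid of the
label's pixels in each frame — the input is a uniform label, so the
centre of mass is the binary centroid. Circle-bearing labels also
recover an area-equivalent radius √(area/π). A label with no pixels in
a frame is recorded as a detection failure for that frame; failures are
reported, never interpolated.

For non-overlapping in-bounds discs the encode→filter→decode round trip
recovers positions within 0.5 px (sub-pixel rasterisation asymmetry)
and exactly at integer centres (lattice-disc symmetry).

## Segmentation backend

Training and running the external 3D segmentation network is out of
scope; the package provides the dataset exporter (with a manifest
grouping all sequences of a shoulder so folds can be assigned at
shoulder level), a thin adapter that shells out to the framework's
prediction tool when installed, and a ground-truth **oracle backend**
used by all tests. Its corruption model emulates the error modes of a
real segmenter at the geometric level the pipeline consumes: rigid
per-disc Gaussian displacement (localisation error — jitter moves whole
discs, not pixels, because the downstream quantity is the centroid),
per-(label, frame) dropout (detection failures) and uniform disc
erosion (under-segmentation). It is deterministic under a fixed seed.
With σ px isotropic jitter the extracted Euclidean error follows a
Rayleigh distribution with mean σ·√(π/2), which the tests verify at
σ = 2 px, n ≈ 2000.

## Calibration

The 25 mm sphere's projected disc gives the scale. Per frame the
area-equivalent diameter 2·√(area/π) is computed (robust to boundary
rasterisation and unbiased for discs, unlike a max-Feret measure); the
sequence scale is 25 divided by the mean diameter, since the sphere is
static and averaging suppresses rasterisation noise. The scale is
isotropic (the detector has square pixels). No magnification or
parallax correction is attempted for out-of-plane sphere placement. On
the phantom the recovered scale is within 0.1% of the true 0.35 mm/px.

## Kinematics

Abduction angle: θ = atan2(|Δx|, Δy) between image vertical and the
glenohumeral-centre → shaft vector, in degrees. Gravity is assumed
aligned with image columns (no gantry tilt is recorded with the
acquisitions). The magnitude convention is unsigned, with left
shoulders mirrored in x so lateral shaft displacement is positive for
both sides. The series is reported raw — no smoothing or interpolation;
frames where either required landmark failed are flagged invalid.
Because the shaft sits on a ~10 cm lever arm, a 2 px (0.7 mm)
localisation error maps to only ~0.4° of angle error.

## Agreement statistics

* **Dice** 2|A∩B|/(|A|+|B|) per label; 1.0 when both sets are empty,
  0.0 when exactly one is.
* **Distances**: mean ± SD (sample SD, n−1) of |Δx|, |Δy| and
  √(Δx²+Δy²), per landmark, in px and mm, optionally stratified by
  pulse rate (3 Hz / 10 Hz / all). Frames with a failure in either
  annotation are excluded pairwise per landmark — not listwise — and
  the exclusion count is reported; failure counts live in their own
  table.
* **Bland–Altman**: d̄ ± 1.96·SD with the fixed Gaussian multiplier
  (not t-based), sample SD.
* **ICC**: the default form is two-way random effects, absolute
  agreement, single measure — ICC(2,1) = (MSR − MSE) / (MSR +
  (k−1)·MSE + k·(MSC − MSE)/n) — because the use case is agreement
  between measurement methods, where systematic offsets must count
  against the coefficient. The CI is the standard F-based interval with
  a Satterthwaite degrees-of-freedom approximation; the implementation
  is cross-checked in the tests against an independent
  variance-components derivation and against `pingouin`. A consistency
  form ("c-1") is available as a config knob. Zero-variance input is
  reported as a degenerate perfect agreement (ICC 1.0, collapsed CI,
  flag set). Note that ICC of a *static* landmark coordinate is near
  zero by construction (no between-frame variance), which is a property
  of the statistic, not a defect of the detector — distance statistics
  are the informative measure there.

## The phantom

The generator emulates the acquisition geometry, not radiometric
physics: a bright humeral-head disc whose centre is the joint centre, a
shaft bar rotated about it by the frame's abduction angle, static
glenoid/acromion marks, the 25 mm sphere, then Gaussian blur, additive
Gaussian noise and optional Poisson noise. Defaults are the nominal
study conditions: 946 × 958 px frames at 0.35 mm/px, a 30° peak, an 8 s
task, and a 10 Hz pulse rate (≈ 80 frames per task, the regime in which
detection is most robust; at 3 Hz the shaft travels farther than its
disc diameter between frames, so sparse sequences should use the 2D
filter mode). The abduction profile is a raised-cosine 0→30→0° ramp —
amplitude is specified for the task, the profile shape is not, and a
smooth symmetric ramp is the minimal assumption — rescaled so the
sampled maximum is exactly the peak for any frame count. 3 Hz sequences
default to stronger blur (σ = 2 px vs 1 px) reflecting the greater
motion blur at longer pulse intervals. Geometry values with no external
reference (joint centre at (425, 316) px, 24 mm humeral-head radius,
100 mm shaft lever, 11 mm shaft half-width, glenoid/acromion offsets of
15–30 mm, sphere at (776, 814) px) were chosen once as anatomically
plausible for a scapular-plane projection and are all configurable.
Noise and blur touch only the images; the emitted ground truth is exact
by construction, so every downstream error measured against it is
attributable to the pipeline stage under test.

**What the phantom does not show.** It contains no real anatomy — no
overlapping bone contours, no contrast variation with tissue thickness,
no scatter or beam hardening, no rater ambiguity about poorly defined
landmarks (the shaft point's position along the axis, the rounded
glenoid edges). Passing tests therefore demonstrate that the codec,
calibration, kinematics and statistics are correct and internally
consistent — not that any particular segmentation model reaches a given
accuracy on clinical images, which depends on trained weights and data
that are out of scope here.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: codec round trips on
500 random landmark sets in 200 × 200 px frames; component-filter
equivalence against an exhaustive flood-fill oracle on volumes up to
32³; jitter statistics on ~2000 landmark instances; the end-to-end
kinematics checks on the full-resolution 81-frame default phantom.
Tolerances follow the error sources: 1e-9 for exact lattice/analytic
identities, 0.5 px for sub-pixel rasterisation asymmetry, 1% for
calibration recovery, 3 standard errors (plus a 0.05 px rasterisation
budget) for Monte-Carlo means. CSV output stores floats at full repr
precision, so write→read round trips are lossless; the coordinates CSV
carries a trailing `radius_px` column beyond the documented
`frame,label,x_px,y_px,x_mm,y_mm,failed` header for exactly that
reason.

## Known limitations

* The largest-component filter's 3D default assumes the inter-frame
  landmark displacement is below the disc diameter; violated at 3 Hz
  for fast-moving landmarks (use `mode="2d"`).
* Calibration ignores out-of-plane sphere magnification.
* The angle convention cannot represent adduction past 0° (unsigned
  magnitude), matching how the task is reported.
* The external-framework adapter is exercised only for its error path
  in CI; running it requires the framework and trained weights.
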