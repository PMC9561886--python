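# Methods

`aclloc` reimplements a fully automated pipeline for localizing the rupture
of the anterior cruciate ligament (ACL) on 3D knee MR volumes and
classifying it as femoral-side, middle, or tibial-side.  This note records
the model, its assumptions, the tunable parameters, what the synthetic
phantoms do and do not establish, and the numerical decisions taken where
the design was genuinely open.

## The pipeline

1. **Segmentation (coarse stage).**  A 3D U-Net (strided-convolution
   downsampling, transpose-convolution upsampling, skip concatenation at
   equal resolution, softmax over four channels: background, femoral
   footprint, tibial footprint, ligament) labels the whole volume.  The
   per-footprint centroids — largest connected component only, so stray
   false-positive voxels cannot drag them — define the ACL axis and the
   region of interest (ROI).
2. **ROI crop.**  A fixed-size voxel box (default 48 x 48 x 16 at
   1 x 1 x 3 mm spacing) centered between the two footprint centroids.  A
   fixed shape rather than a content-dependent bounding box keeps the crop
   compatible with the heatmap network's divisibility contract
   (dims divisible by 2^(depth-1)) and covers the ~38 mm ligament plus both
   footprints with margin.  `roi_from_segmentation` also provides the
   classical margin-dilated bounding box.
3. **Localization.**
   * *3D route (primary):* a second U-Net with a single sigmoid output
     channel regresses a Gaussian probability heatmap on the (z-scored) ROI.
     Decoding thresholds at probability 0.5 and returns the
     probability-weighted centroid of the surviving region in physical mm;
     if no voxel reaches 0.5 the global maximum is used and flagged
     (`fallback_used`), so failure statistics remain honest.
   * *2D route:* the ROI is resampled in-plane to 0.25 mm, padded/cropped to
     256 x 256, and a 6-slice window feeds a slice-selection network (eight
     pairs of 1x3x3 convolutions with in-plane-only max pooling, collapsing
     256 -> 1 over eight halvings, softmax over slices).  The in-plane
     coordinate comes from a single-level detector that reads only the
     deepest feature map and predicts one box; the keypoint is the box
     center, the box size is fixed at the ligament's nominal 11 mm width.
4. **Classification.**  The localized point is projected perpendicularly
   onto the femoral-to-tibial footprint line; dividing the line into three
   equal parts (~12 mm each for a 38 mm ligament), the third containing the
   perpendicular foot gives the side class.

## Training targets and loss

The heatmap target is `exp(-||p - landmark||^2 / (2 sigma^2))`, truncated at
`support_radius` and rescaled so the grid maximum is exactly 1 (attained at
the voxel containing the landmark).  A shell of width `suppression_band`
immediately *outside* the support is flagged invalid and excluded from the
loss — false-positive suppression: the network is not punished for small
responses just beyond the landmark region.  Placing the band inside the
support would erase the target itself, so outside placement is the only
coherent reading.

Training minimizes soft Dice plus focal loss over valid voxels.  Invalid
voxels contribute exactly nothing to either term or its gradient (verified
to 1e-12).  With `focal_gamma = 0`, `focal_alpha = 0.5`,
`dice_weight = 0` the loss reduces analytically to half the binary
cross-entropy, which is unit-tested.

## Parameters that matter

| parameter | default | unit | rationale |
|---|---|---|---|
| `sigma` (heatmap width) | 3 | mm | comparable to slice thickness; keeps the support inside one 12 mm class third |
| `support_radius` | 3 sigma | mm | standard truncation, <1.2% residual mass |
| `suppression_band` | 2 | mm | the "< 2 mm" false-positive band |
| decode threshold | 0.5 | prob. | standard probability threshold |
| failure threshold | 10 | mm | strict: exactly 10.0 mm is a success |
| ROI box | 48 x 48 x 16 | voxels | covers 38 mm ligament + footprints at (1,1,3) mm |
| `dice_weight`/`focal_weight` | 1 / 1 | — | unstated upstream; equal weighting |
| `focal_gamma`/`focal_alpha` | 2 / 0.25 | — | standard focal defaults |
| U-Net capacity | depth 3, 8 channels | — | desk scale: minutes on one CPU core |
| seg-net capacity | depth 2, 4 channels, 12 epochs | — | whole-volume stage kept cheap |
| optimizer | SGD, lr 0.05, momentum 0.9 | — | plain momentum SGD; lr chosen on the training loss only |

Every network runs on z-scored input volumes (per-volume mean/SD); the same
standardization is applied at training and inference.

## The synthetic world

No public dataset exists for this task, so the package ships a phantom
generator: a bright tube (intensity 1.0) of the ligament's nominal 38 x 11
mm dimensions spans two spherical footprint blobs (radius 6 mm, intensity
0.8) along a random chord; intensities within ±`gap_halfwidth` (2.5 mm) of
the rupture fraction along the chord are set to background, and additive
Gaussian noise (SD 0.05) is applied.  The default grid is 64 x 64 x 32
voxels at 1 x 1 x 3 mm — the in-plane/slice anisotropy of a sagittal T2
knee series.  Side labels are always *derived* from the rupture fraction by
the classifier's own rule, never stored independently, so label drift is
impossible.  Dataset composition defaults to the 43/35/7
femoral/middle/tibial proportions of the study population
(largest-remainder rounding).

The chord always runs obliquely with its femoral end superior (slice-axis
component >= 0.3, never inverted), as the ACL does anatomically.  This is
load-bearing: with two geometrically identical footprints and a free
orientation, femoral-vs-tibial would be unlearnable from the image and the
segmentation stage demonstrably collapses.

What the phantoms do **not** emulate: anatomically shaped bones and
ligament, Rician MR noise, bias fields, partial tears, scanner variation.
A green phantom test therefore establishes that the *machinery* —
geometry, targets, losses, decoding, statistics — is correct and that the
networks can recover a planted signal at desk scale; it says nothing about
clinical performance on patient MRI.

Simulated readers annotate the rupture as `gt + bias + N(0, sd^2)` per
axis; with isotropic jitter the mean Euclidean error has the closed
Maxwell–Boltzmann form `sd * sqrt(8/pi)`, which the Monte-Carlo test checks
to 5%.

## Numerical choices and conventions

* **Coordinates.**  All physical coordinates are LPS mm; NIfTI RAS headers
  are converted on read/write.  Voxel indices are 0-based, fractional where
  meaningful; crop boxes are inclusive.  Landmark TSVs store scanner
  physical mm, never patch-local coordinates.
* **Resampling.**  Linear for intensities, nearest for labels; in-plane
  resampling keeps the origin and slice count.
* **Straddle-slice supervision.**  The two integer slices flanking the
  fractional slice coordinate receive weights (1-frac, frac): a linear
  split preserves sub-slice information under cross-entropy.
* **2D inference z.**  The argmax slice (lowest index on ties); a perfectly
  uniform score vector is flagged low-confidence.
* **Centroid decoding.**  Probability-weighted by default (sub-voxel
  stability); an unweighted binary centroid is available
  (`centroid="binary"`).
* **Classification boundaries.**  t = 1/3 and t = 2/3 go to the more
  femoral class; projections outside [0, 1] are clamped, not rejected
  (predictions can overshoot the footprint line yet still deserve a class).
* **Suppression band in the loss.**  Masked out (invalid), not trained as
  hard negatives.
* **Normalization layers.**  Group normalization throughout (batch
  normalization is available; with single-sample training it reduces to
  per-channel instance statistics and is kept as a distinct class so
  architecture audits can tell them apart).
* **Elastic augmentation.**  Seeded coarse displacement grid
  (control-point spacing 8 voxels, max displacement 2 voxels), linear
  interpolation; the landmark is moved by fixed-point inversion of the
  backward warp.
* **Slice-selection pooling.**  Pooling acts on the in-plane axes only —
  the only reading consistent with a 6-long output after eight 256 -> 1
  halvings.
* **ICC/ANOVA.**  ICC(2,1) (single measure, two-way random effects,
  absolute agreement) is computed from the explicit ANOVA decomposition
  with the standard F-based 95% CI and cross-checked against pingouin;
  one-way ANOVA goes through `scipy.stats.f_oneway` and is verified against
  explicit sums of squares.  Degenerate inputs (zero variance) are flagged
  undefined, never coerced.
* **Undefined classification metrics** (zero denominators) are reported as
  NaN, never 0 or 1 — reader confusion matrices are sparse enough that
  silent zeros would mislead.
* **Determinism.**  Every stochastic step takes an explicit seed
  (numpy `default_rng`); training is deterministic single-threaded, and the
  demo's `metrics.json` is byte-identical across reruns (wall times go to a
  separate log).

## Desk-scale capacity

The original system trained a full-resolution nnU-Net variant and a
ResNet-101-backed detector on 8 GPUs; reproducing that is out of scope.
The networks here are deliberately small (depth 3, 8 base channels; the
whole framework is numpy with hand-written backpropagation, since no GPU
framework is available in the target environment).  The bundled experiment
(60 training / 20 held-out phantoms, pinned seed) recovers the planted
rupture to under 4 mm mean error with >= 85% side accuracy in roughly ten
CPU-minutes; these figures are computed by the test suite, not asserted
from above.

## Known limitations

* DICOM support is a minimal explicit-VR little-endian reader/writer
  (uncompressed single-frame slices) written because no DICOM library is
  available in the environment; it is not a general implementation.
* The 2D route's slice window is a fixed 6-slice window centered on the
  ROI; how the original system chose its 6 slices from a 22–39-slice stack
  is unstated.
* Phantom realism is deliberately minimal (see above); localization
  accuracies measured here are not comparable to the published in-vivo
  values, which require the private 85-patient cohort.
* The detector regresses no box size; partial-tear and multi-rupture cases
  are out of scope.
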