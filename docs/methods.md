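# Methods

## Problem setting

MRI voxel intensities are relative quantities: coil sensitivity profiles and
field imperfections multiply the tissue signal by a smooth, spatially varying
*bias field* (shading), and the overall scale differs between scanners and
even between repeat scans. Any voxel-wise MRI-to-CT conversion model is
therefore tied to the intensity scale it was trained on. `mr2ct` implements a
workflow that (1) normalizes the intensities of the three dominant non-bone
tissue classes of the torso — air/lung, soft tissue, fat — to fixed per-tissue
levels, and (2) converts the normalized MRI into a pseudo-CT in Hounsfield
units with a small patch-based convolutional regression network trained on
pointwise MRI–CT intensity pairs. Bone is excluded throughout: in clinical
practice bone HU are composited in from a registered planning CT or an atlas
(`compose_bone`).

## Shading-map normalization

The estimator for the multiplicative field is segmentation-based:

1. **Fuzzy c-means** clusters all voxel intensities into k = 3 classes
   (fuzziness m = 2, the standard default). Cluster centers are initialized
   at the (2j+1)/(2k) quantiles of the intensity distribution, so a run is
   deterministic; iteration stops when the relative center movement falls
   below 1e−4 or after 300 iterations. Clusters map to tissue codes by
   ascending center intensity (air/lung < soft tissue < fat, the contrast
   order of T1-weighted torso imaging). Volumes above 2×10⁶ voxels are
   clustered on a seeded subsample and all voxels assigned from the final
   centers. Clustering covers the *whole* volume; exterior background air
   pools with lung in class 0.
2. **Three-intensity mask**: each voxel is replaced by a fixed bulk level for
   its class. The default table {air/lung 18, soft 65, fat 149} a.u.
   reproduces the corrected-intensity scale of torso imaging and is
   user-overridable — the cohort-derived table the method calls for is
   site-specific and unpublished.
3. **Ratio image** = MRI / mask, computed at every voxel. Inside a correctly
   labeled region the ratio is the bias field times a class-level error.
4. **Shading map** = per-axial-slice 10×10-pixel moving average of the ratio.
   Smoothing is 2-D because in-plane pixels (0.66–1.5 mm) and slice spacing
   (3–8 mm) make an isotropic 3-D window physically anisotropic. Even widths
   use the window [i − w/2, i + w/2 − 1] per axis; borders replicate edge
   values (no dark halo at the body outline); the result is clamped below at
   1e−6 × its median so division is safe in all-air regions.
5. **Correction** = MRI / shading map.

Because the shading map contains only low spatial frequencies, edges survive
division; because the bulk table is fixed, corrected per-tissue means land on
the bulk levels regardless of the scanner's overall gain — this is the
harmonization mechanism across field strengths. The known limitation is a
band of ~half the smoothing width around class boundaries where the window
mixes the ratio levels of adjacent classes; in structures thinner than the
window (a thin subcutaneous fat ring at coarse pixel sizes) this biases the
corrected means by a few percent when the per-class ratio levels differ.

## Rigid MI registration

CT is aligned to MRI by maximizing Mattes mutual information: joint
histograms over a seeded uniform voxel sample (default 50 bins, 500 samples;
tests and the optimizer use larger samples where variance matters), a
zero-order (box) kernel on the fixed axis and a cubic B-spline Parzen kernel
on the moving axis, bin edges at the 1st–99th intensity percentiles of the
overlap. MI = H(f) + H(m) − H(f, m) in nats. The optimizer is derivative-free:
two resolution levels (Gaussian-smoothed 2× decimation, then full), cyclic
coordinate descent over three rotation angles (degrees) and three
translations (mm) with a bounded golden-section line search and a bracket
that shrinks by 0.6 per sweep. The sample set is drawn deterministically from
the config seed, so the objective is coherent along search lines and runs
are reproducible. The recovered transform is the *pull-back* map (fixed
point → moving sample position); registering a volume created by resampling
through T returns T⁻¹. Deformable registration is deliberately not
estimated; `apply_deformation` applies an externally supplied displacement
field (voxel units, pull-back, trilinear).

## Pointwise pairs, templates, patches

Per training slice (default slices 2, 4, 6, 8 as printed, 0-based 1, 3, 5, 7;
validation slice 20) and tissue class, voxels inside the class mask are
sorted by MRI intensity (ties by scan order) and pairs are read at rank
positions ⌊j(M−1)/(n−1)⌋ — 25 for lung and fat, 50 for soft tissue — which
always includes the class minimum and maximum. Rank spacing rather than
intensity spacing is robust to skewed histograms. Soft-tissue pairs split at
the median rank into low/high halves, giving four groups (lung, soft-low,
soft-high, fat). Each group becomes a template pair: a square grid of
constant 40-px blocks (configurable, ≥ 34 px), pairs placed in sorted
row-major order, surplus cells cycling through the pairs. Any layout
satisfying the invariant *every pixel's (MRI, CT) value is an extracted
pair* trains the same pointwise mapping. Training items are random 32×32
crops of the MRI template with the centered 18×18 crop of the CT template as
label.

## Conversion network

Three valid-convolution stages (kernels 7, 5, 5; no padding anywhere), so
32×32 → 18×18 exactly. Hidden stages use 32 channels and a rectifier (a
leak slope is configurable but defaults to 0); the output stage is linear,
one channel. Deep supervision:
1×1 auxiliary regression heads after stages 1 and 2, center-cropped to
18×18, each contributing MSE with weight 0.3 to the total loss. Channel
counts and DSN weights are free parameters of this package (the only hard
architectural constraint is the 32→18 shape arithmetic); 32 channels trains
the recovery tasks to ~2 HU on one desktop CPU core in minutes, and 64 is
available through `ModelSpec`.

Optimization is stochastic gradient descent with mini-batch 128, learning
rate 0.01 and momentum 0.9, minimizing the DSN-weighted MSE. Two numerical
choices make these fixed hyperparameters robust:

- inputs *and* labels are affinely standardized to zero mean / unit variance
  of the training set (predictions are mapped back to raw HU; the stored
  affine is part of the model). Raw-HU targets put the quadratic loss
  curvature far outside the stable step size at this learning rate.
- weights are initialized at 0.3 × the He scale (`init_gain = 0.3`). At full
  He gain the first momentum steps overshoot along the top curvature
  direction of the 800-input output stage; depending on the seed the
  excursion either diverges outright or permanently switches off enough
  rectifier units to cap accuracy. The reduced gain keeps every seed's
  trajectory inside the stable region while leaving the architecture and the
  stated optimizer settings untouched.

Training defaults to 50 epochs with early stopping on validation loss
(patience 10, best weights restored). Runs are deterministic for a fixed
seed on a fixed platform; convolutions are im2col matrix products in
float32.

Whole-volume inference reflect-pads each axial slice by 7 px, tiles 32×32
windows at stride 18 (configurable down to 1) and averages overlapping
18×18 outputs; the pseudo-CT grid equals the input grid. A monotone
piecewise-linear lookup through the intensity pairs ships alongside the
network as a transparent baseline and cross-check.

## Digital torso phantoms

The simulator generates paired MRI/CT volumes with full ground truth: an
elliptical body, a subcutaneous fat ring (outer 10 % of the body radius),
soft-tissue interior, two lung ellipses (chest preset) or a bowel-gas pocket
(abdomen preset), and exterior air. Clean MRI and CT are per-tissue constant
levels — chest MRI {26, 125, 297} a.u. and CT {−800, 35, −108} HU; abdomen
MRI {65, 298, 533} a.u. and CT {−822, 32, −86} HU — matching the uncorrected
per-tissue means of 0.35 T torso and 1.5 T abdominal acquisitions. The MRI
is multiplied by a smooth strictly positive bias field (signed Gaussian
blobs, default amplitude 0.3 and length scale 40 px, renormalized to unit
spatial mean; a linear ramp and a constant field are available) and additive
Gaussian noise (default SD 5 a.u.; Rician available, modeled as the
magnitude of two independent Gaussian channels). Ellipse radii drift
sinusoidally by ±5 % across slices so per-slice statistics vary. Everything
is seeded and reconstructable.

What the phantoms do **not** model: MR physics (no sequence signal
equations, no k-space artifacts), anatomy beyond three classes plus gas,
partial-volume voxels, bone, and motion. Passing recovery tests therefore
demonstrates the estimator's correctness under the stated
piecewise-constant-times-smooth-field model, not clinical performance.

## Evaluation conventions

Per-tissue statistics use the population SD (divide by N) and
CV = 100·SD/|mean| rounded to two decimals; the absolute mean makes CVs of
negative-HU tissues positive. Both whole-volume and per-slice scopes are
emitted (which of the two a published per-slice figure used is ambiguous, so
reports carry both). Histograms take an explicit fixed range, clip outliers
into the edge bins, and always conserve mass. Volume comparisons report
per-tissue mean differences (a − b), antisymmetric under operand swap.

## Problem sizes used in the shipped checks

The recovery suite runs on a 24×256×256 chest phantom (bias amplitude 0.3,
length scale 40 px, noise SD 5); registration recovery on an 8×96×96
phantom with 4000 metric samples during optimization; network recovery on
2000 patches from templates encoding an affine map, trained 30 epochs.
These sizes exercise every code path at desktop scale while keeping a full
run in minutes.
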