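# Methods

This note documents the models and numerical choices behind `pulmostage`:
what each stage computes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## Pipeline overview

A chest-CT slab goes through four stages:

1. **Segmentation** — a region-based active-contour (level-set) model
   isolates the nodule.
2. **Measurement** — equivalent diameter, voxel count, roundness and
   solid/semisolid/nonsolid type of the mask.
3. **Staging** — deterministic TNM lookup: size → TU subcategory, plus
   coded LN (regional lymph node) and DM (distant metastasis) descriptors →
   stage group 1A1 … 4B.
4. **Classification** — a six-block CNN ("M-CNN") predicts the stage group
   directly from the segmented image, trained and evaluated under stratified
   10-fold cross-validation.

## Level-set segmentation

### Model

The contour is the zero level set of a scalar field φ (negative inside).
Evolution descends the two-phase piecewise-constant energy

    E(I1, I2, φ) = ∫ (f − I1)² w_in + ∫ (f − I2)² w_out
                 + γ ∫ w_in + β ∫ δ_ε(φ) |∇φ|,

with `w_in = H_ε(−φ)` a smoothed inside indicator,
`H_ε(t) = ½(1 + (2/π) arctan(t/ε))` and `δ_ε = H_ε′`.  The intensity
representatives I1/I2 are the w-weighted means (global scalars for the
constant-kernel model; Gaussian-localized fields for a finite
`kernel_sigma`, which tolerates smooth background inhomogeneity).  The
update is explicit gradient descent, gated by δ_ε(φ), with the curvature
force computed by central differences (|∇φ| floored at 1e−8).

A parametric snake energy (tension α∫|C′|², rigidity β∫|C″|, edge attraction
−μ∫|∇f(C)|²) is provided as a diagnostic for extracted contours; the
rigidity term is implemented unsquared by default with a squared-variant
flag, since both conventions appear in the literature.  The level set is the
production path.

### Parameters (defaults)

| name | default | meaning |
|---|---|---|
| `epsilon` | 1.5 grid units | Heaviside/Dirac regularization width |
| `dt` | 4.0 | descent step; the line search halves it when a step would raise the energy |
| `gamma` | 0 | area penalty (shrinks the region; used for degenerate-input behavior) |
| `beta_len` | 0 | length penalty; see "Why β defaults to 0" |
| `kernel_sigma` | ∞ (global) | kernel width of the localized means |
| `max_iter` | 500 | iteration cap |
| `rel_tol` | 1e−4 | energy-window stopping threshold (5-iteration window) |
| `stable_iters` | 25 | stop after this many iterations with an unchanged mask |
| `reinit_every` | 10 | signed-distance reinitialization period |
| `n_seed_squares` | 55 | tiled seed squares in the initialization |

Images are min–max normalized to [0, 1] inside `segment_volume`, so these
defaults are intensity-scale-free.

### Numerical choices and why

* **Monotone line search.**  Plain explicit Euler does not guarantee a
  non-increasing energy.  Each step is accepted only if the energy
  (evaluated with refreshed means — genuine alternating descent) does not
  rise; otherwise the step is halved, up to 8 times.  If no decrease is
  possible even at dt/256 the energy is numerically stationary and the
  evolution stops.  The recorded energy trace is therefore monotone by
  construction.
* **Why dt = 4.**  The Dirac gate δ_ε(0) ≈ 0.21 at ε = 1.5; with normalized
  data forces of order 0.3 the interface advances ≈ dt·δ·F per iteration.
  Sub-unit steps would need hundreds of iterations per voxel of front
  motion; dt = 4 moves the front about half a voxel per iteration and the
  line search makes it safe.
* **Why β defaults to 0.**  The discrete length term Σ δ_ε(φ)|∇φ| depends on
  the parametrization of φ, not only on the contour: the flow can lower it
  by flattening |∇φ| near the front instead of moving the front, after which
  any genuine motion (which re-steepens φ) raises the recorded energy and
  deadlocks the monotone search.  At the phantom noise levels
  (σ ≤ contrast/4) the data terms alone give clean masks; the length term
  remains implemented and can be enabled for noisier data (with the
  understanding that the trace may then stall early).
* **Initialization.**  Square seeds (55 by default) are tiled over each
  slice, but only squares whose mean intensity reaches the bright/dark
  split are kept as initial interior; slices with no bright square are
  bootstrapped with the per-slice bright mask.  A uniformly tiled symmetric
  start is a *saddle* of the two-phase energy — the inside and outside means
  coincide, no data force develops, and the seeds collapse.  The bright/dark
  split is Otsu's threshold when the histogram is genuinely bimodal, else
  (tiny nodules, unimodal noise histogram) median + 4·MAD-sigma.
* **ROI cropping.**  Evolution runs inside a bounding box around the seeds,
  grown by half its extent plus 8 voxels.  Inside the ROI the two phases
  have comparable support, so the global means are informative and
  convergence takes tens of iterations; the mask is pasted back into the
  full grid.  This mirrors the clinical workflow of cropping a region of
  interest around the pointed-at nodule.
* **Stopping.**  Either the energy window (relative change < `rel_tol` over
  5 iterations, after a 15-iteration burn-in) or mask stability
  (`stable_iters` iterations without a voxel changing phase).  The second
  rule exists because, after the front stops, the smoothed field keeps
  relaxing and the energy keeps creeping down; an energy-only criterion
  would always run to `max_iter`.
* **Reinitialization** recomputes the exact signed distance from the current
  mask every `reinit_every` iterations, but is accepted only when it does
  not raise the energy, so the monotone trace survives.
* **Sign conventions.**  φ < 0 inside; the inside indicator is H_ε(−φ) and
  the outside weight its complement (equivalently H_ε applied to −φ — the
  two forms of the outside term are algebraically identical).
* **3D handling.**  Slices are segmented independently (vectorized across
  the slice axis, sharing one energy trace and step size); the 3D mask is
  the slice stack, post-processed to its largest connected component.

## Nodule measurement

* **Equivalent diameter**: disc-equivalent from area (2D) or, for volumes,
  the *maximal in-plane* disc-equivalent diameter — TNM size categories are
  a longest-dimension convention, and slab phantoms flatten large nodules
  through-plane, which would bias a volume-equivalent diameter low.  The
  volume-equivalent sphere diameter is available via `mode="volume"`.
* **Roundness** = 4πA/P².  The perimeter is the marching-squares contour
  polyline with its coordinates Gaussian-smoothed (σ = 1.5 polyline points):
  the raw polyline staircases along smooth boundaries and overestimates
  length by ≈ 7% (disc roundness ≈ 0.88), while the smoothed estimate gives
  discs ≈ 1.00, squares ≈ 0.82 (continuum π/4 ≈ 0.785) and monotone decrease
  with eccentricity.
* **Typing** compares the mean interior contrast (relative to a nonzero
  background estimate) against a full-contrast reference: ≥ 75 % solid,
  40–75 % semisolid, < 40 % nonsolid, ties to the upper class.  The
  reference defaults to the 95th percentile of the interior contrast, which
  is right for solid and semisolid nodules but cannot flag a *uniformly*
  faint (nonsolid) nodule — pass a dataset-level `reference_contrast` when
  that matters.  The thresholds mirror the phantom generator's texture
  conventions (half-contrast rim over the outer 30 % of the radius for
  semisolid; 35 % contrast for nonsolid — 35 % rather than 40 % so that the
  tie rule cannot push a nominal nonsolid nodule into the semisolid class).

## TNM staging

Pure lookup with upper-inclusive size boundaries at 1, 2, 3, 4, 5, 7 cm.
DM1 maps to 4A and DM2 to 4B regardless of TU/LN; TU0 with DM0 returns an
explicit NO_TUMOR sentinel (no tumor is not a stage).  TU1/TU2 parent
categories are derived groupings and never returned directly.  The
classifier-facing coarse grouping with 9 classes merges 1A1/1A2/1A3 into 1A
and keeps 4A/4B distinct (merging stage 4 as well would leave 8 labels, not
9); 8- and 11-class groupings are also provided.

## Stage classifier (M-CNN)

Six blocks of [3×3 convolution (same padding) → ReLU → 2×2 max-pool], then
flatten → dropout 0.2 → fully-connected → ReLU → fully-connected → softmax.
The 8 slab slices enter as channels of a 2D convolution.  Training is
minibatch SGD (batch 10) with momentum 0.9, learning rate
lr(epoch) = lr0·10^(−⌊epoch/10⌋), mean cross-entropy loss, optional early
stopping on validation loss (patience 10), inputs standardized with
training-set statistics stored on the model.  Everything is NumPy
(im2col/shifted-GEMM convolutions, first-max pooling tie-break, all
randomness from one seeded generator), so a fixed seed reproduces training
bit for bit.  The final layer is initialized near zero so an untrained
model is near-uniform softmax and the initial loss is ≈ log(n_classes).

Default configuration: 256×256×8 input, channels (8, 16, 32, 64, 128, 256),
4096 hidden units.  The **benchmark profile** used by the desk-scale
experiments is 64×64×8 input, channels (4, 4, 8, 8, 16, 16), 64 hidden
units, lr0 = 5e−3 — sized so a 150-epoch 10-fold cross-validation runs in
minutes on one CPU core while still reaching ≥ 90 % validation accuracy on
the synthetic benchmark.

## Evaluation harness

Stratified k-fold assignment (per-class fold counts differ by ≤ 1; every
class must have ≥ k members).  Metrics are percentages: accuracy, and
one-vs-rest sensitivity (= recall), specificity, precision and FPR,
macro-averaged by default (micro available); undefined ratios are excluded
from the average with a warning, never silently zero.  AUC is the
Mann–Whitney rank statistic with midrank ties, macro one-vs-rest for
multiclass.  `cross_validate` trains a freshly seeded model per fold
(15 epochs per fold by default, 150 total over 10 folds) and appends a
"Mean value" row that is the exact arithmetic mean of the fold rows.

## Synthetic phantoms: what they emulate and what they do not

A phantom is a constant parenchyma slab (intensity 100, arbitrary units)
with one nodule (disc/sphere/ellipsoid) of diameter 4–20 mm and contrast
20–65 by default — the measured ranges of real and simulated screening
nodules — plus additive Gaussian noise (σ = 5 by default, i.e. contrast/8
at mid contrast).  Texture classes: solid (full contrast), semisolid
(half-contrast rim over the outer 30 % of the radius), nonsolid (uniform
35 % contrast).  The ground-truth mask is the noise-free indicator and the
stage label is recomputed from the TNM descriptor, so label consistency is
structural.  A nodule too thick for the 8-slice slab is flattened into an
oblate ellipsoid that fits; the in-plane diameter — the quantity staging
uses — is preserved.

The **9-class benchmark** assigns nine disjoint diameter bins to the nine
stage labels 1A1…3C (2 mm in-plane spacing so a 10 cm nodule fits a 64×64
slab); LN codes are attached only to the TU4 bins where they are needed to
reach distinct labels, because LN/DM are metadata with no image signature —
a class the images cannot encode would be unlearnable by construction.

Not emulated: lung anatomy (vessels, airways, mediastinum, thoracic wall),
attenuation physics and Hounsfield calibration, spiculated or
juxtapleural margins, CT reconstruction texture, PET tracer kinetics.
Passing tests therefore demonstrate that the algorithms are implemented
correctly and behave as designed on controlled geometry and noise — not
that the pipeline reaches clinical accuracy on patient data.

## Problem sizes used by the test suite and acceptance script

On this synthetic benchmark the raw slabs are themselves quite learnable
(the nodule is the only structure present), so the segmentation-first
advantage is a modest, seed-dependent margin rather than the large gap
expected on cluttered clinical images; the ablation asserts the direction
of the effect at a fixed matched seed, not its magnitude.

The cross-validation benchmark in the test suite uses 100 slabs per class
(900 total, 64×64×8) segmented with the benchmark profile (dt 6, ε 1,
max_iter 150 — chosen as the point where further iterations no longer
change the masks of mid-size nodules materially).  The acceptance script
re-runs the same pipeline at 30 slabs per class, which reproduces the same
qualitative results in a few minutes; its ablation compares binary-mask
inputs against raw slabs on a stratified 80/20 split at a matched seed and
15-epoch budget.

## Known limitations

* The global two-phase model assumes a bright object on a darker, roughly
  homogeneous background within the ROI; strong bias fields need the
  localized-kernel mode, and objects darker than background are not
  segmented (by design — nodules are hyperdense).
* Slice-independent segmentation ignores through-plane continuity.
* Roundness is computed on the maximal-area slice of a 3D mask, not as a
  3D sphericity; for objects below ≈ 7 px diameter the pixel-count area
  exceeds the area enclosed by the sub-pixel contour and roundness can
  slightly exceed 1.
* The CNN's stage vocabulary is only as expressive as what the image
  encodes: nodal involvement and metastasis are invisible in single-nodule
  slabs, which is exactly why the deterministic TNM path, not the CNN, is
  the pipeline's source of truth for staging.
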