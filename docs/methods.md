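# Methods

## Problem and approach

Segmenting head-and-neck gross tumor volumes (primary tumor GTVp, nodal
disease GTVn) on T2-weighted MRI is the bottleneck of MRI-guided adaptive
radiotherapy.  At the mid-treatment timepoint a strong prior exists: the
pre-treatment scan and its segmentation, deformably registered onto the
current anatomy.  Assuming effective treatment, the shrunken tumors stay
where they were, so the stale mask is an excellent *localizer* even when it
is no longer an accurate *delineation*.

`stagedseg` implements the staged strategy built on that observation:

1. **Stage 1 / baseline** — a 3D residual encoder-decoder trained with the
   conventional foreground-oversampling patch sampler (a fraction
   `fg_fraction`, 33% by convention, of training patches is centered on a
   reference foreground voxel).
2. **Mask-guided refinement** — a second training run in which every patch
   is centered on a voxel of a prior mask: the stage-1 prediction
   (pre-treatment task) or the registered pre-treatment mask (mid-treatment
   task).  Channel configurations follow the ablation naming used
   throughout the package: *c1* uses the prior for sampling only; *c2* adds
   the prior mask as an input channel; *c3* (mid-treatment) stacks the
   current image, the registered prior image and the prior mask as three
   input channels.  *staged_c3* additionally restricts sliding-window
   inference to windows intersecting the prior mask.

Inference is Gaussian-weighted sliding window: overlapping patches (50%
overlap by default), per-patch softmax probabilities blended with a
separable Gaussian of σ = patch/8 per axis (floor-clamped, max-normalized),
argmax per voxel.  In masked mode, only windows whose extent intersects the
binarized prior run; voxels no window covered are background by contract.

### A note on the masked-inference identity

For any voxel **inside** the ROI every window containing it is retained, so
masked and unmasked blending are bit-identical there.  The same is *not*
guaranteed for covered voxels outside the ROI: such a voxel can lose
contributions from windows that were dropped, so its blended probabilities
— and occasionally its argmax — may differ.  Tests therefore assert exact
agreement on ROI voxels plus the uncovered-is-background contract.

## Network and loss

The network is a compact residual encoder-decoder in the nnU-Net family:
`n_stages` resolutions, residual blocks (two conv–instance-norm–leaky-ReLU
units with an identity or 1×1-projected skip), strided-conv downsampling,
transposed-conv (kernel 2, stride 2) upsampling with encoder skip
concatenation, and 1×1 segmentation heads on the finest `ds_levels` decoder
outputs for deep supervision.  The desk default is 3 stages with channels
(3, 6, 12) and two supervision levels — the smallest width that passes the
single-patch overfit sanity check with margin.  The full-scale
configuration of the underlying family (7 stages, 141M parameters, patch
320×256×64) is representable in `NetConfig`/`StageConfig` and kept in the
`full-scale` preset, but it is a configuration value, not something this
package trains.

The objective is the standard compound loss: batch-pooled soft Dice over
the foreground classes (ε = 1e-5) plus voxel-wise cross-entropy, equally
weighted, evaluated at each supervision level against nearest-neighbor
downsampled targets, with per-level weights halving per coarser level and
normalized to sum to 1.

Because no GPU tensor library is assumed, the network runs on a small
tape-based reverse-mode autodiff engine over NumPy (`_tensor`), with the
hot loops (direct 3D convolution forward/weight-gradient, fused instance
norm, leaky ReLU) JIT-compiled via numba (`_kernels`).  The pure-NumPy
im2col path is kept as the reference implementation; the test suite checks
both backends agree to float32 tolerance, and the loss gradient is verified
against finite differences.  One training step (batch 2, 32³ patch, 3
input channels) takes ≈0.1 s on one CPU core.

## Training schedule

SGD with Nesterov momentum and polynomial learning-rate decay
`lr0·(1−step/total)^0.9`, `lr0 = 0.01`, batch 2.  The full-scale
convention (1000 epochs × 250 steps, momentum 0.99) is preserved in the
`full-scale` preset.  Desk-scale runs use 12 epochs × 50 steps = 600
optimizer steps; at that schedule length momentum 0.99 is unstable — with
multi-channel input it reproducibly collapses the softmax to all-background
within the first tens of steps — so the desk default is 0.9 (configurable).
Augmentation is a reduced set appropriate for phantoms: random flips,
in-plane 90° rotations, global intensity scaling (×U(0.75, 1.25), p=0.3)
and additive Gaussian noise (σ=0.1, p=0.3); geometric operations are
applied jointly to all channels and the target, intensity operations to
intensity channels only (never to the prior-mask channel).  Elastic
deformation, simulated low resolution and gamma augmentation are out of
scope.

Per epoch, validation "pseudo-Dice" (soft Dice of softmax foreground on one
fixed foreground-centered patch per validation case) is recorded; the
best-validation and final weights are both checkpointed, mirroring the
best/final model comparison the evaluation tables support.

Stage-1 priors for the pre-treatment refinement stage are produced by
in-sample inference of the stage-1 model on its own training cohort; no
cross-validated ensembling is used (the study design this mirrors used a
single 120/30 split).  A case whose prior comes back empty falls back to
default sampling with a logged warning — a first-stage miss must not abort
training.

## Synthetic phantoms

Real paired MRI with expert contours is not distributable with a package
like this, so every mechanism is exercised on longitudinal phantoms
(`phantom` module) whose ground truth is analytic:

* grid 48×48×32 voxels at 1×1×2 mm (anisotropic, as clinical MRI is);
* background = 1 + low-frequency smooth field (Gaussian-filtered seeded
  noise, σ=8 mm, amplitude 0.5) emulating bias field / anatomy, plus white
  Gaussian noise (σ=0.3) after 0.5-voxel edge smoothing;
* one GTVp ellipsoid (semi-axes 6–10 mm) and `n_gtvn`=2 GTVn ellipsoids
  (3–5 mm), non-overlapping, radii in mm honored under the anisotropic
  spacing, intensity +3.0 over background (10× the noise σ — deliberately
  easy so small networks learn in minutes);
* two *decoy* blobs: equally bright, unlabeled, placed away from lesions.
  They stand in for non-tumor hyperintensities and give the image-only
  baseline a realistic failure mode — without decoys, "bright = tumor" is
  the right rule and prior conditioning has nothing to add;
* mid-treatment: identical anatomy with every lesion's radii ×
  `shrink_factor` (default 0.7; ellipsoid volume scales with the cube);
* the "registered" prior = pre-treatment image and reference rigidly
  shifted by a random vector of magnitude ≤ `prior_jitter_mm` (default
  2 mm), emulating residual misregistration.  Elastic residuals are not
  modeled.

Ellipsoids make exact oracles possible (voxelized analytic volumes);
generation is bit-reproducible from a single seed, with per-case seeds
spawned from the cohort seed.  What the phantoms do **not** emulate:
anatomy, Rician noise statistics, infiltrative tumor margins, imaging
artifacts, inter-observer contour variability.  Passing the phantom studies
therefore demonstrates that the *mechanisms* (sampling restriction, channel
conditioning, masked inference, metric behavior) work as specified — not
that any particular clinical Dice level would be reached.

## Evaluation

Per-patient DSC per class, and aggregated DSC (aggDSC): intersections and
mask sizes pooled over all patients before the ratio, the challenge-style
score that is robust to a single all-miss case.  When a class is absent
from both prediction and reference the per-case value is defined as 1 and
flagged; flagged pairs are excluded from paired testing.  Configurations
are compared with a two-sided paired Wilcoxon signed-rank test at α=0.05 on
per-patient mean DSC; for ≤15 effective pairs the exact null distribution
is used (enumerated via the rank-sum generating function, midranks for
ties), otherwise the normal approximation with tie correction.  Report
tables carry best/final aggDSC per configuration (×100, two decimals) and
significance stars.

In the desk-scale studies "foreground DSC" means Dice of the binarized
(GTVp ∪ GTVn) foreground: a 32³ patch can contain only a handful of GTVn
voxels, making single-patch per-class Dice degenerate, and the quantity the
mechanism study measures is localization quality.

## Desk-scale study design

* **Overfit sanity** — the desk-default net reaches merged-foreground soft
  Dice ≥ 0.95 on one fixed phantom patch within 200 steps.
* **Mechanism efficacy** — 20-case cohorts (16 train / 4 validation), 32³
  patches, 600 steps per run: mean per-case foreground DSC of `staged_c3`
  must exceed the image-only `c1` baseline for ≥4 of 5 preset seeds.
* **Island artifact** — a c1-style model (mask-guided sampling, image-only
  channels) run with *unrestricted* inference on decoy-bearing phantoms
  labels bright blobs outside the prior; the connected-component counter
  (26-connectivity, components of predicted foreground disjoint from the
  prior) detects them.  The mask-restricted pass cannot produce foreground
  outside its window coverage by construction.  Island *removal* is
  deliberately absent: the artifact is an observed property of the
  configuration, not something to post-process away.

## Numerical and design choices

* Axis convention: arrays are indexed (x, y, z) in the NIfTI affine's axis
  order; only positive-diagonal (axis-aligned) affines are accepted.
  Patches are half-open `[origin, origin+size)`, 0-based.
* "Samples drawn from within the mask" is implemented as patch *center*
  uniform over mask voxels (then clipped to bounds) — the reading that
  maximizes lesion content per patch; mask-restricted *inference*
  eligibility is patch-extent-intersects-ROI — the conservative reading for
  a stale prior whose true lesion may sit near its edge.  The asymmetry is
  intentional.
* GTVp and GTVn are merged for sampling eligibility; no dilation margin is
  added to the prior before sampling (an optional knob defaults to 0).
* The prior mask enters the network as a single raw-integer channel (not
  one-hot); z-score normalization is per whole volume, with near-constant
  volumes mapping to zero.
* Instance-norm ε = 1e-5; Dice ε = 1e-5; Gaussian blending weights floored
  at 1e-3 of the peak; empty-prior and empty-ROI situations degrade to the
  default sampler / unmasked inference with warnings rather than erroring
  at run time.
* Determinism: a cohort seed and stage seed fully determine phantom data,
  patch/augmentation draws and weight init; repeated runs on one CPU are
  bit-identical (the JIT kernels are sequential and fastmath-stable on a
  fixed machine).

## Known limitations

* The convolution engine is CPU-only and sized for patches of ~32³ at a few
  channels; it is not a general deep-learning framework.
* Phantom realism is intentionally minimal (see above).
* No test-time augmentation, model ensembling, resampling of mismatched
  grids, or DICOM input.
* The exact Wilcoxon path enumerates up to n=15; beyond that the normal
  approximation is used.
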