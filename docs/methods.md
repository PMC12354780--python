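# Methods

## Phantom model

The generator renders what the downstream method needs to see, not anatomy:
an elliptical liver (semi-axes 22 × 16 px in the 64 × 64 desk profile, jittered
by up to 4 px), 0–3 tumor blobs, additive Gaussian noise, and intensities
clipped to [0, 1]. Tumors are discs deformed by a three-harmonic radial
perturbation of 5–20 % of the radius, so their boundaries are irregular enough
to exercise the boundary-sensitive loss terms; each blob is re-sampled until it
lies entirely inside the liver (error after 200 attempts). Default intensity
levels — background 0.15, liver 0.55, tumor contrast +0.25, noise SD 0.04 —
give a tumor-to-liver contrast-to-noise ratio around 6, which is deliberately
an *easy* segmentation problem: passing the desk benchmark shows the training
machinery works end-to-end, not that the method would meet clinical-grade CT
performance. Real CT features the phantom does not emulate: organ context,
partial-volume effects, scanner-dependent noise texture, lesion
heterogeneity, 3-D continuity. Sample *i* of a dataset uses seed
`spec.seed + i`; every stage downstream is seeded, so the whole pipeline is
bit-reproducible.

The tumor count is uniform on {0,…,3}, so three quarters of slices carry at
least one lesion; per-slice labels for stage 2 are tumor present/absent.

## Preprocessing

Order: min–max normalization → luma grayscale (0.299/0.587/0.114, RGB inputs
only) → bilateral filter → Gaussian blur → resize → z-score standardization,
with augmentation (when enabled) applied between resize and z-score on
training rows only. The bilateral filter uses the standard two-kernel form —
spatial `exp(−d²/2σ_s²)`, range `exp(−ΔI²/2σ_r²)` on intensity differences —
with window radius `ceil(2σ_s)` (≥ 95 % of the spatial Gaussian mass) and
reflect padding. The Gaussian blur uses the same window and border
conventions, which makes the σ_r → ∞ limit of the bilateral filter equal the
blur to machine precision — a property the tests rely on. Defaults:
σ_s = 1.5 px, σ_r = 0.1 intensity, blur σ = 0.5 px; normalization is
per-slice.

Splits use largest-remainder apportionment of n·(0.7, 0.2, 0.1) with ties
going to later-listed splits. This is the unique simple rounding rule that
reproduces all published instance-count rows this package mirrors
(201→141/40/20, 2658→1860/532/266, 2187→1531/437/219, 6407→4485/1281/641);
nearest-rounding fails on the 2658 row.

Augmentation follows one canonical inventory — rotations {80°, 90°, 180°,
270°}, horizontal/vertical flips, contrast scaling 0.9–1.1, spatial scaling
0.95–1.05 — image and mask share every geometric transform, masks resampled
nearest-neighbor so labels stay categorical, oblique rotations bilinear on
the image. CLAHE and elastic deformation are deliberately out of scope to
keep a single well-defined augmentation set.

## Network

Encoder level k runs `inception_modules` blocks at width `base_filters·2^k`:
parallel branches with kernels {1, 3, 5}, each k > 1 branch preceded by a 1×1
channel reduction (the classic inception economy; without it the 5×5 branches
dominate compute), concatenated to the nominal width, plus a residual add
(1×1-projected when the input width differs). A 1×1 "levelled bottleneck"
then compresses channels by `bottleneck_ratio` (default 0.5) before 2×2 max
pooling. The decoder mirrors the ladder with nearest-neighbor upsampling + 3×3
convolution (avoids checkerboard artifacts of transposed convolutions),
concatenating the skip connection and a *historic stamp* — a trained 1×1
projection of the same cached encoder map — before inception fusion. Every
convolution is followed by BatchNorm → ReLU → Dropout; the head is a 1×1
convolution with sigmoid. An optional bottleneck pyramid-pooling block
average-pools at scales {1, 2, 4}, 1×1-projects each scale to width/3
channels, upsamples and fuses back with a 1×1 convolution. Weights are
He-uniform, seeded. A 512-input, 4-level configuration bottoms out at 32 × 32,
matching the full-scale design; the desk profile (64 px, 2 levels,
8 base filters, ≈ 23 k parameters) bottoms out at 16 × 16.

The network runs on a small tape-based numpy autodiff engine
(`uigo.autodiff`) written for this package: NCHW tensors, im2col convolutions
(with a matmul fast path for 1×1), max/avg pooling, nearest upsampling,
batch normalization with running statistics, inverted dropout, and Adam.
Everything is single-threaded float64; gradients are verified against central
differences in the test suite.

## Losses

* **Focal** (defaults α = 0.25, γ = 2, the standard retinal-detector values;
  the source text states neither): predictions are clipped to
  [1e−7, 1−1e−7] before the log.
* **Dice**: soft, on the unit scale with smoothing ε = 1.0 in numerator and
  denominator. The percentage-scale constant that sometimes appears in print
  ("100 −") is treated as a typo: a ~99-valued Dice term would swamp the
  4 %-weighted Hausdorff term by three orders of magnitude. The *training
  loop* evaluates Dice per slice and averages (`per_sample=True`): a single
  global sum over a batch gives small lesions a vanishing gradient share and
  in practice stalls threshold crossing; the per-slice form is what mainstream
  segmentation frameworks compute.
* **Hausdorff surrogate**: exact Hausdorff is non-differentiable, so training
  uses `mean(p·d_T² + (1−p)·t·d_P²)/diag²`, where d_T is the distance
  transform to the target, d_P the distance transform to the thresholded
  prediction, and diag the image diagonal (so the value is scale-free in
  [0, 1]). Conventions: both masks empty → 0; an empty set's distance field is
  taken as diag. The surrogate is strictly monotone in blob displacement and
  rank-correlates with exact Hausdorff (Spearman ≥ 0.8 on random mask pairs).
* **Composite**: 0.27·FL + 0.69·DL + 0.04·HD, weights overridable, components
  logged per epoch.
* **Tversky / focal-Tversky** (α = 0.7, β = 0.3, γ_ft = 0.75): soft counts
  with smoothing s = ε/2 = 0.5 so that α = β = 0.5 coincides exactly with the
  Dice loss at its default smoothing.

## Metrics

Confusion-count metrics with zero-denominator cases returning 0 plus a flag
(all-background slices are legal); Dice/IoU with the both-empty → (1, 1)
convention; exact symmetric Hausdorff over foreground coordinates
(`scipy.spatial.distance.directed_hausdorff`; one empty mask → image diagonal,
flagged); rank-statistic AUC. Pixel-level AUC uses a stratified ~1 % pixel
subsample — full-pixel ROC costs memory without changing the estimate
materially. A diagonal-normalized Hausdorff is provided for comparability
with normalized reports. Multi-class evaluation is one-vs-rest per structure.

## Gravitational optimization

The update scheme is the canonical gravitational-search algorithm (the source
describes the mechanism but never prints update equations): fitness-linear
masses normalized to sum 1, attraction from a Kbest elite shrinking linearly
from the full population to `kbest_final` (default 4 %, i.e. one attractor at
the end for the default population of 25), G(t) = g₀·e^(−βt/T) with the
literature defaults g₀ = 100, β = 20, velocity `rand·v + a` with the mass
cancellation `a_i = Σ_j rand·G·m_j(x_j−x_i)/(‖x_j−x_i‖+1e−12)` applied
algebraically so the worst (zero-mass) particle still moves. Positions are
clamped to bounds; minimization throughout. The binary variant flips bit d
with probability |tanh(v_d)|, repairs empty subsets to the best single
feature, caches subset evaluations, and absorbs scorer failures as
worst-so-far fitness. Hyperparameter tuning encodes log-scale parameters in
log10 space and rounds integer parameters on decoding. `converged_at` reports
patience-based stagnation; the default budget (25 particles × 100 iterations)
drives the 5-D sphere below 1e−3 from any tested seed, typically to ~1e−17.

## Stage 2

Eight-connected components of area ≥ 5 px each yield a row of 12 regional
features (area, perimeter, eccentricity, solidity, mean/SD intensity,
skewness, kurtosis, and GLCM contrast/homogeneity/energy/correlation at
offset 1 px, 0°, 32 gray levels with masked-level renormalization); the
per-sample vector adds component count, total area, max component area and a
has-regions flag, with the regional features taken from the largest component
(zeros when the prediction is empty). Bounding boxes are half-open
[min, max), 0-based, row-major. The LightGBM booster runs deterministic,
single-threaded, with stratified 5-fold CV (clamped to the minority-class
size). The GO wrapper fitness is 3-fold CV error of a small booster plus a
sparsity penalty λ·|subset|/d, λ = 0.05.

## Pipeline and problem sizes

`run_pipeline` executes forge → split → train → predict → features → GO
selection → classifier → evaluation, each stage resumable from its artifacts,
with a JSON summary of all metrics. Checkpoints are single `.npz` files with
the network configuration embedded.

The desk profile trains 200 phantoms (140/40/20) at 64 × 64 for up to 12
epochs, batch 8, Adam at the published 1e−3, early stopping on validation
Dice (patience 6) with best-checkpoint restoration, and
reduce-on-plateau × 0.5 after 5 stagnant epochs. Desk-scale deviation: dropout
0.1 instead of the full-scale 0.3 — desk inception branches carry only 2–4
channels, where 0.3 per-pixel dropout routinely zeroes entire feature maps
and makes the train-mode and eval-mode networks diverge; the full-scale
default remains 0.3. Under these conditions validation Dice reaches
0.97–0.98 across seeds (≈ 2–3 minutes on one CPU core). The acceptance script
runs exactly this profile plus the GO benchmarks; its reproducibility check
uses a reduced 48-phantom, 32-pixel configuration run twice, which exercises
the identical code path.

## Known limitations

* The phantom task is nearly intensity-separable; results say nothing about
  performance on real CT.
* Eval-mode batch-norm statistics lag the fast-moving weights in very short
  trainings; best-checkpoint selection on validation Dice is what makes the
  reported numbers stable.
* The Hausdorff surrogate penalizes misplaced mass, not the true maximum
  deviation; it is a training signal, not a metric.
* The historic-stamp and pyramid-pooling blocks implement one concrete
  reading of briefly described design elements; both are flag-gated so their
  contribution can be ablated.
* K-fold training of the segmentation network at full scale is supported by
  the harness but not exercised in the test suite (cost); the harness is
  validated with fast runners.
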