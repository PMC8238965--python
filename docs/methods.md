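# Methods

`octseg` segments macular edema — pockets of serous fluid that appear as
dark (hypo-reflective) regions inside the bright layered retinal bands of
an OCT B-scan. The pipeline has three scientific stages plus a synthetic
data source and an evaluation harness. This note records the models, the
parameters that matter, and the design decisions taken where the design
was genuinely open.

## Synthetic B-scan phantoms

Clinical OCT volumes are not distributed with this package; every
experiment instead runs on phantoms that emulate the *statistical*
structure of B-scans with edema:

* **Geometry** — a curved, tilted retinal band spanning the full image
  width, subdivided into `n_layers` horizontal sub-bands with gray levels
  in [0.5, 0.75]; the surround (vitreous) sits at 0.08. Fluid pockets are
  rotated ellipses with a low-order radial wobble (so boundaries are not
  perfectly smooth), semi-axes drawn from `pocket_scale_range`, placed
  entirely inside the band; their gray level (default 0.15) is strictly
  below every band, as real fluid is hypo-reflective.
* **Speckle** — fully developed speckle is modelled as a multiplicative
  gamma field with shape `speckle_looks` and mean 1 (variance
  `1/looks`), the standard coherent-imaging noise model. The default
  `looks = 4` gives pronounced granularity (σ/µ = 0.5) while leaving the
  bands recognizable, a level we consider representative of a single
  moderately averaged B-scan. The unclipped float field is kept in
  memory; writing 8-bit PNGs clips to [0, 1] (sensor saturation).
* **Patient structure** — one dataset-level seed fans out deterministically
  (`SeedSequence(seed, spawn_key=(patient, scan))`) to per-scan streams,
  so patient-level splits and cross-validation folds are meaningful.

What the phantoms do *not* model: real layer anatomy and pathology-driven
morphology changes, axial PSF anisotropy, shadowing under fluid, mirror
artifacts, vignetting, or the lesion-size distribution of any clinical
cohort. Passing phantom experiments therefore demonstrates that the
pipeline's machinery works as specified — not clinical-grade accuracy.

## Wavelet despeckling

B-scans are decomposed with a 2-level 2-D DWT (default family `haar`,
symmetric boundary handling; `haar` is orthonormal, so reconstruction of
an untouched pyramid is exact to float rounding and coefficient energy
equals pixel energy). A single noise threshold

    NT = median(|p|) / alpha

is estimated from the pooled coefficients of the bands selected for
shrinkage (`threshold_scope="per-image"`, the default; `"per-band"`
computes one NT per subband). With the default `alpha = 0.6745`, NT is
the classical MAD estimate of the noise standard deviation. Coefficients
are then soft-thresholded (`sign(p) · max(|p| − NT, 0)`) and the image
reconstructed and clipped to [0, 1].

Which bands to shrink is a policy choice. The default `details` shrinks
the LH/HL/HH bands at every level — standard wavelet shrinkage;
thresholding the approximation band instead (`"low"`) is also available
for comparison, but it attacks the image's DC content and is not
recommended. On speckled phantoms the default configuration gains about
+2 dB PSNR against the known clean image (the acceptance script
recomputes this number).

## Coarse segmentation network

A DeepLab-style encoder–ASPP segmenter implemented directly in NumPy
(NCHW float32, hand-written backward passes; convolutions are computed
as sums over kernel taps of shifted slices, which makes atrous dilation
free and keeps the parameter count independent of the rate).

Architecture (tiny profile, the default): a 3×3 stem into 16 channels,
one 2× average-pool (output stride 2), then two stages of two
pre-activation residual blocks (`x + f(x)`, f = BN–ReLU–conv ×2), the
second stage dilated ×2 at 32 channels; ASPP with rates {2, 4, 8} plus a
global-pooling branch, fused by 1×1 convolution; a 1×1 classifier; and
bilinear upsampling of the logits to input resolution followed by
softmax. A `full-scale` profile records the conventional large
configuration (4 stages of 3/4/23/3 blocks, base 64, ASPP {6, 12, 18})
but is not exercised.

Training follows the standard recipe for this model family: SGD with
momentum 0.9 and weight decay 5e-4 on per-pixel cross-entropy, initial
learning rate 0.007 decayed by the poly schedule
`lr0 · (1 − t/T)^0.9`, batch size 8. The validation split (patient
level) selects the checkpoint by best validation F1. All randomness —
init, shuffling — derives from `TrainConfig.seed`.

**Class weighting.** Fluid occupies only a few percent of phantom pixels.
Under the fixed budget (≤ 20 epochs ≈ 500 SGD steps on 200 phantoms) the
unweighted loss leaves the minority class badly under-segmented
(sensitivity ≈ 0.65) while the loss is still falling when the schedule
ends. The default loss therefore weights pixels 1 : 4
(background : fluid), which restores the precision/sensitivity balance
within the same budget. Weighting can be disabled via
`TrainConfig(class_weights=None)`.

Problem sizes: the package's reference experiment trains the tiny
profile on 200 phantoms of 64×64 px (25 patients × 8 scans, 60/20/20
patient split) for 20 epochs; the four-arm ablation ordering is assessed
at 48×48 px and 10 epochs over 5 seeds. These sizes are the package's
desk-scale study conditions; at this scale a training run takes a few
minutes on one CPU core.

## Dense-CRF boundary refinement

The coarse probability map defines unary potentials
`ψ_u(X_i) = −log P(X_i)`; all pixel pairs are coupled through a Potts
compatibility times a weighted sum of Gaussian kernels, the principal one
bilateral:

    k(i,j) = exp(−|p_i−p_j|²/2θα² − |f_i−f_j|²/2θβ²)

with features f the gray values of the (denoised) image **on the 0–255
scale** — the scale on which the default θβ = 8 is meaningful. θα = 16 px
and θβ = 8 are the defaults, matching the F1 optimum of the sensitivity
sweep (`sweep_theta` evaluates the full θα, θβ ∈ 1..20 grid — 400
points — and reports the surface, the per-fixed-θα curves and the
argmax). An optional second, spatial-only smoothness kernel (scale
`theta_gamma`) realizes the M = 2 variant.

**Kernel normalization (design decision).** The raw pairwise sum grows
linearly with the number of similar pixels, i.e. with image area; on
anything beyond toy sizes the messages then swamp the unary evidence and
inference collapses to per-intensity-cluster majority votes (we observed
whole pockets erased at 64×64). The kernels are therefore symmetrically
degree-normalized by default, `k̂(i,j) = k(i,j)/√(d_i d_j)` with
`d_i = Σ_j k(i,j)`, the convention of standard dense-CRF inference code;
this keeps messages O(1) at every image size. Normalization is applied
identically in the energy, the mean-field updates and the brute-force
oracle, so all three optimize the same objective;
`kernel_normalization="none"` recovers the literal raw-sum model. On the
normalized scale the default coupling ω = 3 was calibrated once, jointly
against three behaviors: refinement must improve phantom F1, must repair
an isolated wrong pixel of unary confidence up to 0.9 inside a
homogeneous region, and must keep ≥ 90% agreement with the exhaustive
MAP on random 3×3 problems.

Inference is mean field with fixed iteration count (default 10; no
convergence test):

    Q_i(l) ∝ exp(−ψ_u(l) − Σ_{l'} µ(l,l') Σ_m ω_m Σ_{j≠i} k̂_m(i,j) Q_j(l'))

initialized from the softmax of the negated unaries. Two backends
compute the messages: `dense` materializes the N×N kernel matrices
(exact; used automatically up to 1500 pixels), `filtered` approximates
the bilateral sum by splat → Gaussian blur → slice on a
(y/θα, x/θα, f/θβ) grid with unit sigma (degrees for the normalization
are obtained by filtering a field of ones). The grid quantization is
nearest-cell; on images with sharp fluid/band contrast — the regime this
pipeline operates in — filtered and dense labelings agree to ≥ 95%. In
dense mode the returned labeling is additionally guaranteed never to
have higher Gibbs energy than the unary argmax (the argmax is returned
if a fixed-iteration run ends worse). `brute_force_map` enumerates all
labelings (|L|^N ≤ 2^20, chunked) and breaks ties toward the
lexicographically smallest labeling; it is the oracle for the inference
tests. The Gibbs normalizer Z is never computed — only energies are
compared.

Degenerate inputs: non-finite unaries are rejected; a probability of
zero is clipped at `eps = 1e-10` before the log; labels outside the
label set raise.

## Evaluation

Pixel confusion counts give precision `tp/(tp+fp)`, sensitivity
`tp/(tp+fn)`, specificity `tn/(fp+tn)` and F1 `2tp/(2tp+fp+fn)`. A
metric with zero denominator is reported as 0 with a `RuntimeWarning`
rather than raising, so batch evaluation never aborts. Aggregation is
per-image mean ± sd by default (pooled-pixel aggregation is available).
Probability maps are binarized at 0.5, ties to background. ROC curves
sweep all distinct thresholds (scikit-learn), AUC is trapezoidal and
equals the pairwise rank statistic; the tests verify this against a
brute-force pairwise oracle, plus the analytic limits 1.0 (perfect) and
0.5 (chance). Cross-validation partitions *patients*, never scans, into
k deterministic folds.

## Pipeline modes

`plain` (network only), `wt` (despeckle before training and prediction),
`crf` (refine after prediction) and `full` (both) mirror the classical
ablation arms. In `wt`/`full` the CRF consumes the denoised image as its
feature source; in `crf` it consumes the raw image — each arm uses only
what it has. All hand-offs go through files; one structured run log
records every stage, seed, parameter and timing, and the global seed
makes a rerun bit-reproducible.

## Known limitations

* The phantom task is far easier than clinical segmentation; reported
  F1/AUC values characterize the machinery, not clinical performance.
* The NumPy network is CPU-bound and deliberately small; the
  `full-scale` profile is recorded but not trainable in reasonable time
  here.
* The filtered CRF backend quantizes with nearest-cell splatting; for
  θα close to 1 the grid equals the pixel grid (exact in position), but
  for large θα on small images the spatial quantization is coarse.
* Mean field is a local method; the energy guarantee is relative to the
  unary argmax only, not global optimality.
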