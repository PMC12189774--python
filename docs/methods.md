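# Methods

`nucleotex` classifies histopathology tiles of the three Philadelphia
chromosome-negative myeloproliferative neoplasm subtypes — essential
thrombocythemia (ET), polycythemia vera (PV), and primary myelofibrosis
(MF) — by combining two complementary feature families: interpretable
handcrafted texture descriptors computed inside segmented nuclei, and
high-dimensional deep tile embeddings from an external pathology
foundation model. A third, stacked model is trained on the concatenated
class probabilities of the first two. This note documents the models,
the parameters that matter, the numerical conventions, and the limits of
what the synthetic benchmark can show.

## Preprocessing

Raw 8-bit sRGB images are gamma-expanded with the piecewise sRGB
transfer function and mapped to linear CIE XYZ with the standard D65
matrix, giving a device-independent representation whose Y channel is a
perceptual luminance scalar. All single-channel work downstream
(segmentation, texture) uses this Y channel. Each channel is then
percentile-normalized: the p_low percentile maps to 0 and p_high to 1,
with clipping. Defaults are (1.0, 99.8), the convention of the StarDist
segmentation family; both are configurable. A constant channel has no
contrast to stretch and is left all-zeros with a warning.

Tiling is a non-overlapping row-major grid (default side 256, stride =
side). Edge remainders are dropped, never padded — padded pixels would
fabricate tissue texture. Coordinates are 0-based (row, col) with
half-open extents. Tiles destined for the foundation-model embedder are
bilinearly resized to 224×224 with output clipped to the input range.

## Segmentation

Nuclei masks come from any backend satisfying a one-function contract:
normalized luminance raster in, same-shape integer label raster out.
The StarDist 2D adapter forwards the published operating point
(probability threshold 0.65, NMS threshold 0.1); the network itself is
an external pretrained artifact and is never reimplemented. The builtin
fallback — global Otsu threshold, minority side taken as foreground,
4-connected components — is deterministic and keeps the whole pipeline
runnable offline. Label ids are compacted to 1..n. Per-nucleus patches
are cropped to tight bounding boxes; regions under `min_area` (default
15 px) are discarded and a `border_policy` optionally drops regions
touching the image edge (default keeps them). The filters are explicit
knobs, not inferred intent: no particular quality filter is canonical
for this problem.

## Handcrafted texture descriptors

Within each nucleus the luminance values are quantized by per-patch
min–max binning into G = 32 levels (configurable): level =
⌊(v − min)/(max − min)·G⌋ clipped to G−1, constant patches mapping to
level 0. Per-patch binning makes the matrix features invariant to the
nucleus's absolute brightness; the absolute intensity information is
retained separately by the first-order statistics, whose moments, min,
max and median are computed on the raw masked gray values (entropy alone
is taken base-2 over the G-level histogram). Moments use the population
(n) denominator and kurtosis is non-excess; single-pixel patches take
skewness and kurtosis 0 by convention.

Three matrix families are built mask-aware — pairs, runs and zones never
cross the nucleus boundary:

* **GLCM** over distances D = {1,2,3} and angles Θ = {0°,45°,90°,135°},
  directional (unsymmetrized) accumulation; with rows increasing
  downward, angle θ uses the offset (Δrow, Δcol) = (−d·sinθ, d·cosθ).
  Features per matrix: contrast Σ(i−j)²P, correlation
  Σ(i−μᵢ)(j−μⱼ)P/(σᵢσⱼ) (defined 0 when a marginal deviation vanishes),
  energy ΣP², homogeneity ΣP/(1+|i−j|).
* **GLRLM** over the same four angles: maximal equal-level runs along
  each scan line, broken at mask boundaries. Features: SRE
  (Σ N(r)/r²)/N_runs, LRE (Σ r²N(r))/N_runs, run percentage, and the
  Galloway gray-level and run-length nonuniformities.
* **GLSZM** under 4- and 8-connectivity: connected equal-level zones.
  Features: SZE, LZE (the zone-size analogues of SRE/LRE), zone
  percentage, gray-level nonuniformity.

The per-nucleus vector concatenates, in fixed order, 8 FOS values,
4 GLCM features × 12 (d,θ) pairs, 5 GLRLM features × 4 angles, 4 GLSZM
features × 2 connectivities, plus nucleus area and bounding-box aspect
ratio: 86 named values. Degenerate sub-operations (e.g. a (d,θ) offset
with no valid pair) contribute flagged zeros, never NaN. Nuclei are
pooled to one sample vector per tile by per-feature mean and population
standard deviation plus the nucleus count (173 values) — a
permutation-invariant aggregation that is independent of how many nuclei
a tile happens to contain. All three matrix builders are verified
against exhaustive brute-force enumeration of pairs, runs and zones on
random masked patches.

## Embeddings

The embedding stage is a contract: tile in, fixed-length finite vector
out, constant dimension across a dataset (violations are hard errors).
The H-optimus-0 adapter (ViT-g/14, 1536-dim, 224×224 input) forwards
tiles when its optional dependency stack is installed; the transformer's
internals are out of scope here. The deterministic surrogate embedder
computes a fixed bank of 30 tile summary statistics — per-channel means
and variances, an 8-bin gradient-magnitude histogram, a 4×4 grid of
luminance block means — and projects them through a pseudorandom
Gaussian matrix derived from a seed. It is a testing device, not a
pathology model: it preserves exactly the intensity/texture contrasts
the synthetic generator encodes and nothing more. Precomputed embedding
CSVs (sample_id, e0…) are accepted as a first-class input so real
deep embeddings never need to be computed inside this package.

## Classifier stack

A tile is the sample unit for both branches, so the stacked
concatenation aligns one-to-one; tiles inherit their image's label, and
splits are stratified by image (all tiles of an image stay on one side).
Each block is a scaler → selector → classifier pipeline:

* scalers: standardization, min–max, robust, max–absolute;
* selectors: RFE (logistic-regression eliminator, 10% step), PCA
  (component count additionally capped by the sample count), mutual
  information; the selector keeps ⌈keep_fraction·n_features⌉ features,
  and keep_fraction 1 is the identity;
* classifiers: logistic regression, linear and RBF SVM, random forest,
  gradient boosting, k-NN, SGD with log loss, MLP, Gaussian naive
  Bayes, decision tree. Margin classifiers without native probabilities
  expose softmax-calibrated probabilities over their decision scores.

Model selection maximizes the composite weighted-average metric — the
plain mean of support-weighted precision, recall, F1, accuracy, and
specificity (one-vs-rest TN/(TN+FP), support-weighted) — on a held-out
15% split. The search is a tree-structured Parzen estimator over the
categorical space (numeric hyperparameters enter as small grids): after
10 random startup trials, trials are split at the top quartile into
good/bad sets, smoothed categorical densities l and g are estimated per
parameter, 24 candidates are drawn from l and the one maximizing
Σ log l/g is evaluated. The sampler is implemented in
`nucleotex.search`; it follows the standard TPE recipe and is exact for
categorical spaces. Every trial is appended to a replayable history;
the best trial is the composite argmax with ties to the earliest.

Stacking is leakage-controlled: block 3's training features are
out-of-fold probabilities from 5-fold stratified cross-fitting of the
tuned first-stage configurations within the training split; the
first-stage models are then refit on the full training split to produce
the test-side probabilities. Naive stacking on in-sample probabilities
would be optimistically biased. Blocks are tuned sequentially (1, 2,
then 3), and multi-run experiments either retune every run
(`retune="always"`, default) or reuse the first run's configurations
(`"once"`). Default trials per block: 50.

## Statistical validation

Per-run metric series are summarized by mean and sample (n−1) standard
deviation — the population denominator is used only inside the texture
moments, and the two contexts are deliberately separate. The one-sample
t-test uses t = (mean − ref)/(sd/√n) with two-sided p from Student t
(n−1 df); Cohen's d = (mean − ref)/sd and Hedges'
g = d·(1 − 3/(4n−5)). The reference value must be chosen by the
analyst; `ref="mean"` reproduces the circular convention of testing
against the sample mean (t = 0, d = g = 0 by construction) and the
report flags it as such. Normality is assessed by Shapiro–Wilk,
Jarque–Bera, and a one-sample Kolmogorov–Smirnov test against
Normal(mean, sd) with estimated parameters (no Lilliefors correction,
matching common practice; its p values are therefore conservative
against normality). Zero-variance series are degenerate for all three
tests and return p = 0 with a flag. The t-test's type-I error is
verified by Monte Carlo at the nominal 5% level.

## Synthetic data

The generator produces 256×256 tiles with exact nucleus label masks in
three separable texture regimes, phenomenologically inspired by the
subtypes' morphology and never claimed biologically faithful:

| recipe | nuclei/tile | radius (px) | intensity μ/σ | grain | clustering |
|--------|-------------|-------------|---------------|-------|------------|
| PV-like | 12–18 | 4–7 | 0.30 / 0.09 | 0.7 | 0.15 |
| ET-like | 5–8 | 9–13 | 0.45 / 0.05 | 2.5 | 0.85 |
| MF-like | 8–12 | 6–9 | 0.38 / 0.13 | 1.5 | 0.40 |

Grain is the Gaussian correlation length of within-nucleus noise;
clustering interpolates uniform placement toward aggregation around a
few hubs; the MF-like background is anisotropically smoothed (σ = 2×16)
for a streaky fibrous look. Nuclei are ellipses placed with rejection
against overlap (a 1-px moat keeps them 4-disconnected) and bounded
retries; packing failure raises. All randomness flows from one master
seed through per-tile child seeds drawn once, so any tile regenerates
independently. The values above were chosen once as a plausibly
separable three-class benchmark at desk scale.

What the synthetic benchmark does **not** show: real H&E color
statistics, stain variation, overlapping/touching nuclei, segmentation
errors of a real model, or class differences as subtle as real MPN
subtypes. Passing the end-to-end recovery test demonstrates that the
pipeline machinery — features, tuning, stacking, metrics — is correct
and leak-free, not that these descriptors reach any particular accuracy
on clinical material.

## Problem sizes and numerical choices

The end-to-end benchmark uses 30 tiles per class (seed 7), the
64-dimensional surrogate embedder, 25 TPE trials per block, and 10
tuned runs; the oracle-equivalence suite uses 200 random 6×6 masked
patches at G = 4. These sizes were chosen so the whole suite runs
comfortably on a single CPU while leaving the statistical checks
well-powered. Ties in the TPE search resolve to the earliest trial;
degenerate texture matrices yield flagged zeros; probability rows are
validated to sum to 1 within 1e-9 before concatenation; misaligned
sample ids are hard errors, never silently reordered.

## Known limitations

* The builtin segmenter is a thresholding fallback; on real tissue it
  under-segments touching nuclei. Real use should supply StarDist or
  file masks.
* The surrogate embedder is linear in 30 summary statistics; it cannot
  stand in for foundation-model embeddings on real images.
* Aggregation to tile level by mean/std discards the nucleus-count
  distribution's higher structure (e.g. spatial arrangement).
* With ~90 samples the 15% test split is small (14 tiles), so per-run
  metrics are coarse-grained; the multi-run machinery exists precisely
  to average over this.
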