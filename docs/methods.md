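# Methods

This note documents the models, conventions and numerical choices behind
`drfusion`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, and what the synthetic test bed does and does not show.

## Enhancement

The enhanced image is `mean_k(g) − ∇²g`, computed on the green channel `g`
of the gray-world-corrected RGB image.

* **Gray-world constancy.** Each channel is scaled by
  (mean of channel means)/(channel mean), then clipped to [0, 1]. Before
  clipping the three channel means are exactly equal. A channel with zero
  mean cannot be rescaled and is rejected as degenerate.
* **Mean filter.** A k×k box (default k = 4) normalized by the true pixel
  count k². Even kernels have no center pixel; we anchor at the top-left
  pixel of the central 2×2 block, so the window spans offsets
  −(k/2−1) … k/2 per axis. All borders are reflect-padded (symmetric,
  edge pixel repeated), which preserves constants exactly.
* **Laplacian.** The discrete 4-neighbor stencil [[0,1,0],[1,−4,1],[0,1,0]]
  with the same reflect border. It annihilates affine images on the
  interior and maps x² to the constant 2 — both asserted in tests.
* The fused output is deliberately **unclipped** (the Laplacian term is
  signed): feature extraction wants the real-valued response. A 16-bit PNG
  export path min–max rescales for visualization and records the limits in
  a JSON sidecar.
* Enhancement uses the green channel because retinal microvasculature has
  its strongest contrast there; a luminance variant is available via
  `channel="luminance"`, and constancy can be bypassed (`color_constancy=False`),
  in which mode enhancement is exactly linear in `g`.

## Handcrafted descriptors (232 = 16 + 13 + 203)

* **FCH (16).** A fuzzy histogram over a scalar color index. The default
  index is green dominance, `(G − (R+B)/2 + 1)/2 ∈ [0,1]`, chosen because
  vessels and red lesions suppress green locally while exudates raise it;
  a plain luminance index is available. Bin centers sit at `(i+0.5)/16`;
  each pixel contributes triangular membership to its two nearest centers
  (memberships sum to 1; values beyond the outermost centers belong fully
  to the edge bin). The histogram is normalized to sum 1. FCH is computed
  on the constancy-corrected RGB image, since it needs color.
* **GLCM (13).** The image is min–max quantized to 16 gray levels (a
  constant image quantizes to level 0 and is flagged). Co-occurrence
  matrices for distance 1 at 0°/45°/90°/135° are made symmetric and
  normalized individually, then averaged. The 13 classical Haralick
  statistics are returned in the canonical f1…f13 order: ASM, contrast,
  correlation, variance, inverse difference moment, sum average, sum
  variance, sum entropy, entropy, difference variance, difference entropy,
  and the two information measures of correlation. Logarithms are natural;
  `0·log 0 = 0`; correlation of a zero-variance matrix is defined as 0 and
  IMC1's normalizer `max(HX,HY)=0` likewise falls back to 0.
* **LBP (203).** 24 neighbors on a circle of radius 2 (5×5 pixel support),
  bilinearly interpolated on a reflect-padded image, thresholded at the
  center with ≥. Codes are labeled by the non-rotation-invariant uniform
  scheme: all-zeros, all-ones, one label per (run length 1–23 × start
  position) uniform pattern, plus a single non-uniform label — 555 labels
  total. The label histogram is then re-binned into exactly 203 equal-width
  bins (label ℓ → bin ⌊ℓ·203/555⌋) so the feature width matches the
  published 232-dim layout; 203 is a compatibility convention, not a
  standard pattern count. GLCM and LBP operate on the enhanced image and
  are invariant to global offset and positive scaling by construction
  (min–max quantization; order-preserving comparisons). One caveat: where
  an interpolated neighbor is *exactly* equal to the center (constant
  patches), the ≥ threshold sits on a floating-point knife edge and a code
  can flip by one ulp's worth under affine remapping; on continuous-valued
  images such ties have measure zero and the invariance is exact.

These descriptors are authored here rather than delegated, because the
required conventions (13-statistic Haralick set, the exact padding,
labeling and re-binning rules above) must match the package's brute-force
oracles bit-for-bit; each is verified against per-pixel/pair-enumeration
reference implementations in the test suite.

## Deep-style embeddings and PCA

The embedding stage is a **seeded random filter bank**, not a trained
network: two rounds of (5×5 zero-padded convolution → ReLU → 2×2 average
pooling, stride 2), depthwise in round two, then a global average per map,
tiled and truncated to exactly 4096 entries. Weights are drawn once from
`uniform(−1,1)/25` with seed 1742 (default), making every embedding a
deterministic, Lipschitz function of the image — a property asserted with
an explicit bound ‖ΔE‖∞ ≤ ‖W₁‖₁·‖W₂‖₁·ε for a one-pixel perturbation ε.
With 64 filters the embedding carries 64 informative dimensions; tiling to
4096 honors the fused-layout arithmetic while remaining honest about rank.
A genuinely pretrained backbone can replace this stage behind the same
out-dim contract.

PCA is fitted by SVD of the mean-centered matrix (mathematically the
covariance eigendecomposition, which the tests cross-check via an explicit
`eigh` route). Components are orthonormal, ordered by decreasing variance,
and signed so each component's largest-magnitude loading is positive. The
component count is capped at `min(k, n−1, d)` with k = 1024 by default, so
small corpora remain valid; requesting an infeasible k reports the maximum.

## Dataset design

* **Curation**: keep `round_half_up(0.1·N)` of the normal class (seeded
  uniform subsample). From 25,810 raw normals this yields 2581 = 21.69% of
  the curated 11,897-image corpus.
* **Split** (per class): `test = round_half_up(0.2·N)`,
  `val = round_half_up(0.2·(N−test))`, `train` the remainder. Round-half-up
  is the unique simple rule that reproduces every published per-class cell
  from the curated totals. Assignment of images to partitions is seeded and
  stratified; partitions are disjoint and exhaustive.
* **Augmentation** (training partition only — validation and test are never
  augmented): fixed factors normal 3, mild 3, moderate 1, severe 11,
  proliferative 13 extra images per original, which balances the five
  classes (6608/6252/6774/6696/6342 from the reference train counts). Each
  copy applies one transform drawn from {rotation ±5–25°, horizontal flip,
  vertical flip, shift ≤5% of the side}, reflect-filled, shape- and
  label-preserving; the rotation/shift ranges are small on purpose so
  pinpoint lesions are not destroyed, and are config-exposed. Flips are
  used at most once per image so the k copies are pairwise distinct.
  Synthetic corpora are generated balanced, so the pipeline's default
  factor for them is 1 per class (the augmentation path stays exercised
  without inflating balanced data); the published factors remain the
  defaults for imbalanced manifests.

## Classifiers

* **Hybrid-SVM**: standardize (training statistics) → RBF SVM, C = 1,
  gamma = 'scale' (kernel/C config-exposed; the max-margin solver is
  delegated to libsvm via scikit-learn). Prediction takes the argmax of
  one-vs-rest decision values; `predict_proba` is a softmax of those
  values — a ranking score for ROC curves, not a calibrated probability.
* **Fusion-FFNN**: standardize → single hidden layer of 15 logistic units →
  softmax, cross-entropy loss, seeded mini-batch gradient descent (Adam)
  with early stopping on an internal 10% fold, patience 20, ≤500 epochs
  (scikit-learn's MLP underneath). "15 hidden units in one layer" is the
  standard pattern-net reading of the design; output rows sum to 1 within
  1e−9.
* Ties in the argmax go to the lower class index. Identical config + seed
  gives identical predictions end-to-end.
* **Fusion** is plain concatenation `deep ‖ fch ‖ glcm ‖ lbp` (1024 + 232 =
  1256 at full scale; the deep block shrinks with the PCA cap on small
  corpora). Standardization belongs to the classifiers so slicing a fused
  matrix recovers its blocks exactly.

## Evaluation

One-vs-rest per class: TP is the diagonal cell, FN the row remainder, FP
the column remainder, TN everything else; accuracy, precision, sensitivity
and specificity per class (in %), macro-averaged into the report scalars,
with micro accuracy (trace/total) alongside. For binary problems macro
one-vs-rest accuracy and micro accuracy coincide. Classes with no true
samples are excluded from macros with a warning. Per-class accuracy is
reported as per-class recall. Two AUC modes exist: `roc` (default) is the
macro one-vs-rest ROC area from the probability matrix; `eq11_ratio`
(sensitivity/specificity·100) is retained only for comparability with
reports that define AUC as a TPR/FPR ratio — the two disagree in general
and the ratio is not a true area.

## Synthetic corpus

Each image: circular aperture, orange base color with radial falloff,
smoothed low-frequency illumination noise plus fine sensor noise, a bright
optic disc, and six dark-red vessel walks from the disc. Lesions are added
per grade with Poisson counts (mean dots/blobs/specks/curves):

| grade | microaneurysms | hemorrhages | exudates | neovascular curves |
|---|---|---|---|---|
| normal | 0 | 0 | 0 | 0 |
| mild | 8 | 0 | 0 | 0 |
| moderate | 18 | 4 | 3 | 0 |
| severe | 30 | 10 | 8 | 0 |
| proliferative | 40 | 14 | 10 | 4 |

Dot radii are 1–2 px and blob radii 3–6 px so lesions survive the 4×4 mean
filter. The microaneurysm rate rises strictly with severity, hemorrhages
rise from moderate on, and neovascularization is exclusive to the
proliferative grade — mirroring the clinical biomarker ladder. Per-image
RNG streams are spawned from one seed, so corpora are byte-identical across
runs and independent of generation order.

What this shows and does not show: the generator guarantees the feature
classes are separable in principle (normal vs proliferative handcrafted
features reach ≥95% leave-one-out accuracy, asserted in tests), with
realistic *overlap between adjacent grades* from Poisson count variation.
Passing the end-to-end thresholds therefore demonstrates that the pipeline
machinery extracts and exploits the discriminative signal it was designed
for — not that it would reach any particular accuracy on real fundus
photographs, which add camera variation, anatomy, grader noise and far
larger images.

## Problem sizes and determinism

Test and acceptance runs use 128×128 images (128 is configurable;
full-resolution fundus images are ~3500×3000) and corpora of 100 images per
class for end-to-end checks, 20–100 per class elsewhere — sizes chosen so
the whole suite runs on a laptop-class single core in minutes. All
randomness flows through explicit seeds (corpus generation, partition
assignment, augmentation draws, filter-bank weights, classifier
initialization); every reported number is reproducible from the config and
seed recorded in each run's provenance JSON.

## Known limitations

* The filter-bank embedding is a stand-in with rank ≤ n_filters; it is not
  a learned representation and underperforms what a pretrained CNN would
  contribute to the fusion.
* FCH internals follow this package's definition (green-dominance index,
  triangular membership); other FCH formulations exist.
* The 203-bin LBP re-binning merges unrelated uniform patterns by label
  adjacency; it trades descriptor purity for the fixed published width.
* `eq11_ratio` AUC is not an ROC area; it is off by construction whenever
  specificity ≠ 100% and is never used by default.
* Metrics macro-average over classes present in the test set; with very
  small per-class test counts the macro scalars are coarse (steps of
  1/n_test).
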