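# Methods

This note records the models implemented in `lesionkit`, the assumptions
behind them, the synthetic data they are exercised on, and the numerical
and design choices a maintainer would want to know about.

## Data model

A dataset is a set of annotated images `(X_n, Z_n, U_n, y_n)`.  `X_n` is an
RGB array; `Z_n` a non-empty set of lesion bounding boxes stored
center-based, `(x, y, w, h)` in continuous 0-based pixel coordinates; `U_n`
the per-box lesion types from the closed 8-type taxonomy; and `y_n` the
image-level malignancy label, *derived* (never stored) as 1 iff any box
type lies in the malignant set 𝓜 = {MEL, BCC, AKIEC}.  Conversion to
half-open corner intervals `[x_min, x_max) × [y_min, y_max)` happens only
inside area/overlap computations.  Boxes extending past the image are
clipped at load time with a logged warning; a box with zero area after
clipping is an error.  Dataset splitting is at the patient level (all
images of a patient on one side), seeded.

On-disk interchange is COCO-style JSON (categories = the 8 type codes,
boxes in corner format) plus PNG images; the reference per-type lesion
counts and mean-area statistics ship as small CSVs inside the package.
The square-side equivalent of a mean area is reported as the integer
square root (floor), which reproduces the published per-dataset values.

## Learnable components

All networks share a deliberately small, pure-NumPy convolutional engine:
four 3×3-conv + ReLU + 2×2-max-pool blocks (the backbone is truncated
after the 4th block), global average pooling, and one fully connected
head — sigmoid for binary outputs, softmax otherwise.  Optimization is
minibatch SGD with momentum 0.9 and weight decay 1e-4 throughout.  The
engine is float32, CPU-only, and bit-reproducible given a seed; it exists
so that every stage is trainable in seconds at desk scale without a
deep-learning framework.  A `resnet50` backbone option names the
full-fidelity architecture; selecting it raises, since pretrained deep
backbones are outside this package's scope.

**Crop-level malignancy classifier.**  The region under a box, expanded by
`crop_padding_fraction` (default 0.1) per side, clipped, and resized
anisotropically (bilinear) to a square input, is classified
malignant/benign.  Defaults follow the full-scale recipe: 120 epochs,
batch 64, initial learning rate 0.01, half-period cosine decay
`η(t) = η₀·[0.5 + 0.5·cos(tπ/T_max)]`, resize/rotate augmentation
(right-angle rotations, ±15% zoom).  Desk-scale runs use a 32-px input
and fewer epochs.  Non-square regions are squashed rather than
letterboxed; predicted probabilities are clipped to (1e-7, 1−1e-7) so the
output is strictly inside (0,1).

**Lesion detector.**  A region-proposal detector in two parts.

1. *Proposals.*  The image is resized so its long side equals `work_side`
   (default 128 px) — this fixed working resolution is also what makes
   detection approximately invariant to input rescaling.  A contrast map
   (Euclidean color distance from the median background color, with
   near-black pixels excluded so a dermoscopy vignette is not mistaken
   for a lesion) is smoothed at `fpn_levels` pyramid scales derived from
   the 5th–95th percentile of training box sizes (data-driven anchors).
   Each smoothed map is thresholded at the Otsu level and at 0.55× that
   level; connected-component tight boxes become proposals, each further
   refined by re-thresholding the raw map inside the component window
   (this splits neighbouring lesions merged by smoothing).  Maps whose
   dynamic range is below 12 intensity units are skipped, so blank skin
   yields no proposals.

2. *Scoring.*  A (C+1)-way softmax network classifies proposal crops,
   where C is the label granularity: 1 (*one-class*), 2 (*malignancy*),
   or 8 (*sub-type*).  Training labels proposals by IoU against the
   annotations (≥ 0.5 positive, < 0.3 background, in between ignored),
   adds jittered copies of the annotations and random background boxes,
   and samples up to `proposals_per_image` (default 512) regions per
   image — the "batch per image" is the sampled-region count, the
   standard region-proposal meaning.  The schedule is step decay (10× at
   the 2/3 and 8/9 fractional milestones, the full-scale 60k/80k-of-90k
   positions rescaled to the actual step count), 25 epochs, initial rate
   0.001.  Detection confidence is the predicted class against
   background, `p_c/(p_c + p_bg)` for the best foreground class `c` —
   class-wise detection semantics, under which spreading probability
   mass over many granular classes lowers confidence while a one-class
   head is unaffected.  Detections below `score_threshold` (default 0.5)
   are dropped; greedy NMS (IoU > 0.5) removes duplicates, and a
   containment rule additionally suppresses boxes nested inside a
   higher-scoring box (overlap > 0.75 of the smaller area), which would
   otherwise survive NMS with low pairwise IoU.  Outputs are sorted by
   descending score, clipped to the image, with foreground class
   probabilities renormalized into (0,1)^C.  The score and NMS thresholds
   are explicit package defaults, not values inherited from the
   full-scale study, which does not report them.

**Image-level strategies.**  *Direct*: the crop classifier applied to the
whole image.  *Two-stage*: detect (any granularity; one-class by
default), score each detected box with the crop classifier, aggregate.
*One-step*: a malignancy- or sub-type-granularity detector whose per-box
class vectors are reduced to malignancy probabilities — the "malignant"
entry for C=2, the sum over 𝓜 for C=8 (the measure-consistent reduction;
the reduction for C=8 is not pinned down elsewhere, so this is a package
decision).  Aggregators: average, maximum, noisy-OR
`1 − Π(1 − p_i)`.  A variant `noisy_or_as_printed` computes `1 − Π p_i`;
that form *decreases* as per-box malignancy rises and is degenerate for
its stated purpose, so it is not the default but is kept for comparison.
Images with zero detections fall back to a configurable behavior:
a fixed prior (default 0.0) or the direct model when attached.
Aggregation inputs are sorted before reduction so the result is exactly
permutation-invariant in floating point.

**Clinical and combined models.**  The covariates-only model is logistic
regression (scikit-learn, weak regularization, capped iterations) on
standardized numeric covariates and one-hot categoricals.
Standardization statistics come from training rows only and are reused at
prediction (no leakage).  Zero-variance covariates are dropped with a
warning; missing numerics are mean-imputed; categoricals get an explicit
"missing" level; a level unseen in training maps to an all-zero indicator
block with a warning.  The combined model keeps the fitted crop
classifier as a frozen feature extractor — convolutional parameters are
hashed before and after fusion training and must be identical — and
trains one fully connected sigmoid head on [standardized covariates,
pooled features] with SGD (30 epochs, batch 64, rate 0.001, cosine).

## Evaluation metrics

ROC AUC and average precision use the trapezoid rule over the set of
observed prediction values as thresholds with strict exceedance
(`score > t`), closed by a virtual below-minimum threshold; precision at
the zero-prediction end is anchored at 1.  Under these conventions the
AUC equals the pairwise concordance probability with ties counted ½ (the
test suite verifies both metrics against independent brute-force oracles
to 1e-12).  Detection metrics: greedy score-descending one-to-one
matching, IoU ≥ t inclusive; detection AP with recall measured against
the number of ground-truth boxes, all predictions pooled across images
as one class; mAP at 0.5, 0.75, and the mean over 0.50:0.05:0.95.
Recall at IoU > 0 is the fraction of ground-truth boxes touched by any
prediction with strictly positive overlap.  The IoU distribution summary
(median, Q1, Q3, linear-interpolation quantiles) is computed per
prediction over best-match IoU, zero-overlap predictions contributing 0;
a per-ground-truth variant is available behind a flag since the
published phrasing admits either reading.

## Synthetic data

The generator emulates the structure of a smartphone dermatology
collection; defaults are the package's study conditions and are not
retuned per experiment:

* ~9% of images are dermoscopy-style (one centered lesion at 55–75% of
  the frame inside a circular vignette); the rest are wide-field with
  1–4 lesions.
* Lesion linear size is uniform in 0.10–0.30 of the image side
  (mean 0.2, matching ≈554-px lesions in ≈2834-px images); image sides
  are 96–160 px at desk scale.
* The lesion-type mix follows the packaged reference frequencies
  (57% malignant overall; DF and VASC at 1% each, so two types are
  naturally rare).
* Backgrounds are textured skin in three tone presets
  (light/medium/dark at 83.7/14.9/1.4%), recorded as metadata only — no
  computation is defined over tone.
* Lesions are ellipses with low-frequency radial boundary perturbation;
  malignant types shift pigment toward dark brown/blue-grey, gain
  stronger border irregularity and an off-center darker core, all scaled
  by `appearance_separation` ∈ [0,1]; benign types are lighter and
  smooth.  Pigment bases are chosen so every lesion type is visibly
  darker than every background preset.  At separation 1 and zero noise a
  plain luminance threshold separates malignant from benign crops
  perfectly, so the downstream learning tasks are solvable by
  construction.
* The ground-truth box is the tight bounding box of the rendered mask;
  lesions overlapping an existing one by more than 20% of the smaller
  box are re-sampled, and after 30 failed placements the image is
  emitted with fewer lesions and a warning.
* Everything derives from one seed; identical seeds give bit-identical
  pixels and boxes.

Covariates are simulated per image.  In the default *conditional* mode
labels come from the rendered lesion types and each numeric covariate is
a class-conditional Gaussian with unit SD on the standardized scale and
means ±effect/2, so its implied logistic coefficient equals the stated
effect; categorical levels are re-weighted by `exp(effect)` for
positives.  In *covariate-driven* mode the label is re-drawn as
Bernoulli(sigmoid(intercept + Σ effects)) — used for coefficient-recovery
checks.

What the generator does **not** model: hair, rulers, specular highlights,
illumination gradients, camera variation, or realistic lesion texture.
Passing tests therefore demonstrate that the pipeline's machinery —
detection geometry, probability plumbing, aggregation, fusion, metrics —
is correct and that the models can learn a genuine appearance signal;
they say nothing about accuracy on real dermatological images, and the
desk-scale scores (often near-perfect at high separation) must not be
read as clinical performance.

## Benchmark and problem sizes

`run_benchmark` trains, per run: one crop classifier and one whole-image
classifier (40 epochs), and three detectors (one per granularity,
12 epochs) on 60 simulated training images, then evaluates on 40 test
images.  It emits a granularity × {mAP@0.5, mAP@0.75, mAP@[0.5,0.95],
recall, IoU summary} table, a 4-strategy × {AUC, AP} table, a
3-detector × 3-aggregator grid (two-stage scoring), and a clinical
ablation (clinical-only vs image-only vs combined with no-signal
covariates, plus the frozen-backbone check).  Each cell is wrapped so a
failure is recorded in place and the run continues.  All stage seeds
derive from `global_seed` via CRC32-named substreams, so stages stay
decoupled.  A full run takes roughly two minutes on one CPU.

## Known limitations

* The proposal stage assumes lesions are darker than the surrounding
  skin in color distance; it would miss hypopigmented lesions.
* The tiny backbone saturates on the synthetic benchmark; relative
  comparisons between granularities and strategies at desk scale are
  noisier than at full scale, and individual orderings can flip across
  seeds.
* Box localization comes from proposal geometry (there is no learned
  box regression), so localization quality is bounded by the contrast
  map.
* The combined model fuses at crop level; per-image fusion of multiple
  crops reuses the standard aggregators.
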