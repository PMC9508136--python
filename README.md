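# lesionkit

Two-stage skin-lesion identification and malignancy prediction for clinical
dermatological images — wide-field smartphone photographs that may contain
several lesions, and close-up dermoscopy captures with a single centered
lesion.  The package is aimed at people building or studying screening
pipelines: it detects every lesion in an image, scores each detected region's
likelihood of malignancy, and aggregates region scores into an image-level
probability suitable for triage.  A synthetic-data generator makes the whole
pipeline trainable and testable on a laptop CPU with no external data.

## The model

An annotated image is `(X, Z, U, y)`: an RGB image `X`, a non-empty set of
lesion bounding boxes `Z = {z_i}` with `z_i = (x_i, y_i, w_i, h_i)` (center,
width, height), per-box lesion types `U` from an 8-type taxonomy
{MEL, NV, BCC, AKIEC, BKL, DF, VASC, OB}, and the image label
`y = 1` iff any box type lies in the malignant set
𝓜 = {MEL, BCC, AKIEC} (AKIEC includes squamous cell carcinoma).

Three learned components compose into an image-level score:

* **Lesion identification** `g_ψ(X) = {(ẑ_i, p̂_i)}` — a region-proposal
  detector over a multi-scale pyramid, trainable at three label
  granularities *C* ∈ {1 (*one-class*), 2 (*malignancy*), 8 (*sub-type*)};
  each detection carries a class-probability vector `p̂_i ∈ (0,1)^C` and a
  confidence score, thresholded and de-duplicated by non-maximum
  suppression.
* **Malignancy prediction** `f_θ(X, z) = p(u ∈ 𝓜 | X, z)` — a
  convolutional classifier on the image region under a box: 4-block conv
  backbone, global average pooling, fully connected sigmoid head, trained
  with SGD (momentum 0.9, weight decay 1e-4) under the half-period cosine
  schedule `η(t) = η₀ · [0.5 + 0.5 cos(tπ/T_max)]`.
* **Image classification** `h_φ(X) = p(y=1|X)` by one of three strategies —
  *direct* (whole-image classifier), *two-stage*
  `a({f_θ(X, ẑ_i)})` over detected boxes, or *one-step*
  `a({reduce(p̂_i)})` from a granular detector — where `a(·)` is a
  permutation-invariant aggregator: average, maximum, or noisy-OR
  `1 − Π(1 − p_i)`.

Clinical covariates enter either alone (logistic regression on standardized
numeric + one-hot categorical inputs) or fused with images (covariates
concatenated with the frozen backbone's pooled features, then a fully
connected sigmoid head).

The evaluation suite implements trapezoid-rule ROC AUC and average
precision over the observed prediction thresholds, box IoU, greedy
one-to-one matching, class-pooled mAP at IoU 0.5 / 0.75 / [0.5,0.95],
recall at IoU > 0, and median/IQR IoU summaries.

## Worked example

```python
import numpy as np
from lesionkit import (
    SimConfig, generate_dataset, crop_dataset,
    LesionDetector, MalignancyCropClassifier,
    ImageMalignancyScorer, StrategySpec, roc_auc,
)

train = generate_dataset(SimConfig(seed=11), 60)
test = generate_dataset(SimConfig(seed=12), 40)

detector = LesionDetector(granularity="one_class", epochs=12, seed=3).fit(train)
crops, labels = crop_dataset(train, input_side=32)
classifier = MalignancyCropClassifier(input_side=32, epochs=40, seed=5).fit(crops, labels)

scorer = ImageMalignancyScorer(
    spec=StrategySpec(strategy="two_stage", aggregator="maximum"),
    detector=detector, crop_model=classifier,
)
probs = scorer.predict_proba(test)
y = np.array([im.label() for im in test])
print(f"image-level AUC: {roc_auc(probs, y):.3f}")

result = detector.detect(test[0])
print(f"{result.m_hat} lesions detected, top score {result.scores[0]:.2f}")
```

Output on the seeds above:

```
image-level AUC: 1.000
2 lesions detected, top score 1.00
```

On this high-separation synthetic benchmark the two-stage pipeline ranks
every malignant-containing image above every benign one (AUC 1.0); the
detector finds both rendered lesions in the first test image with a
saturated confidence score.  Harder conditions (lower
`appearance_separation`, more noise) give intermediate AUCs.

The same flow is available from the shell:

```bash
lesionkit simulate --n-images 60 --seed 11 --out data/
lesionkit train-detector --data data/annotations.json --out det.joblib
lesionkit train-classifier --data data/annotations.json --out clf.joblib
lesionkit predict --data data/annotations.json --detector det.joblib \
    --classifier clf.joblib --out probs.csv --detections-out dets.json
lesionkit evaluate --annotations data/annotations.json --detections dets.json \
    --image-probs probs.csv --out report.json
lesionkit benchmark --seed 1 --out bench.json
```

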