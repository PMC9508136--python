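"""Evaluation metrics for malignancy scoring and lesion detection.

Classification metrics (ROC AUC, average precision) are computed with the
trapezoid rule over the set of observed prediction values used as thresholds,
with strict ``score > t`` exceedance:

    TPR_t = p(score > t | y = 1),   FPR_t = p(score > t | y = 0),
    PPV_t = p(y = 1 | score > t).

A virtual threshold below the minimum score closes the curve at
(FPR, TPR) = (1, 1); precision at the zero-prediction end is anchored at 1.
Under these conventions the trapezoid AUC equals the pairwise concordance
probability with ties counted 1/2.

Detection metrics follow the community convention: greedy score-descending
one-to-one matching of predictions to ground-truth boxes at an IoU
threshold, detection AP with recall measured against the number of
ground-truth boxes, all predictions pooled over images as a single class,
and mAP reported at 0.5, 0.75 and averaged over 0.50:0.05:0.95.  Recall at
IoU > 0 counts ground-truth boxes touched by any prediction with strictly
positive overlap.  IoU distribution summaries (median, Q1, Q3) use
linear-interpolation quantiles over per-prediction best-match IoU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .taxonomy import RoiBox

__all__ = [
    "roc_auc",
    "average_precision",
    "iou",
    "ScoredPredictionSet",
    "match_detections",
    "map_at",
    "recall_and_iou_summary",
    "COCO_THRESHOLD_RANGE",
]

COCO_THRESHOLD_RANGE = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def _validate_binary(labels: np.ndarray) -> None:
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")


def _curve_points(scores: np.ndarray, labels: np.ndarray):
    """Unique descending thresholds plus a below-minimum closing threshold."""
    thresholds = np.concatenate([np.unique(scores)[::-1], [-np.inf]])
    above = scores[None, :] > thresholds[:, None]  # (T, N)
    return thresholds, above


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoid-rule area under the ROC curve.

    Equals the probability that a random positive outranks a random
    negative, with ties counted one half.  Raises if only one class is
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _validate_binary(labels)
    n_pos, n_neg = int(labels.sum()), int((1 - labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    _, above = _curve_points(scores, labels)
    tpr = above[:, labels == 1].mean(axis=1)
    fpr = above[:, labels == 0].mean(axis=1)
    return float(np.trapezoid(tpr, fpr))


def average_precision(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Trapezoid-rule area under the precision-recall curve.

    Thresholds are the observed prediction values; precision at the
    zero-prediction end of the curve is anchored at 1.  Raises when no
    positive labels are present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _validate_binary(labels)
    if labels.sum() == 0:
        raise ValueError("average_precision needs at least one positive")
    _, above = _curve_points(scores, labels)
    tp = above[:, labels == 1].sum(axis=1)
    npred = above.sum(axis=1)
    tpr = tp / labels.sum()
    ppv = np.where(npred > 0, tp / np.maximum(npred, 1), 1.0)
    return float(np.trapezoid(ppv, tpr))


def iou(a: RoiBox, b: RoiBox) -> float:
    """Intersection-over-union of two boxes (half-open corner convention)."""
    if a.area <= 0 or b.area <= 0:
        raise ValueError("iou requires positive-area boxes")
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return float(inter / (a.area + b.area - inter))


@dataclass
class ScoredPredictionSet:
    """Per-image scored predicted boxes plus ground-truth boxes.

    ``predictions`` maps image id to a list of ``(box, score)``;
    ``ground_truth`` maps image id to a list of boxes.  Every predicted
    image id must appear in the ground-truth mapping.
    """

    predictions: Mapping[str, Sequence[tuple[RoiBox, float]]]
    ground_truth: Mapping[str, Sequence[RoiBox]]

    def __post_init__(self) -> None:
        extra = set(self.predictions) - set(self.ground_truth)
        if extra:
            raise ValueError(
                f"predictions for images absent from ground truth: {sorted(extra)}"
            )

    def n_ground_truth(self) -> int:
        return sum(len(v) for v in self.ground_truth.values())


def _sorted_preds(preds: Sequence[tuple[RoiBox, float]]):
    return sorted(preds, key=lambda p: -p[1])


def match_detections(
    pred_set: ScoredPredictionSet, iou_threshold: float
) -> dict[str, list[tuple[float, bool]]]:
    """Greedy one-to-one matching of predictions to ground truth.

    Per image, predictions are visited in descending score order and each is
    matched to the unmatched ground-truth box of highest IoU provided that
    IoU >= ``iou_threshold`` (inclusive).  Returns, per image, the list of
    ``(score, correct)`` flags in descending-score order.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    out: dict[str, list[tuple[float, bool]]] = {}
    for image_id, preds in pred_set.predictions.items():
        gts = list(pred_set.ground_truth[image_id])
        taken = [False] * len(gts)
        flags = []
        for box, score in _sorted_preds(preds):
            best_j, best_iou = -1, -1.0
            for j, gt in enumerate(gts):
                if taken[j]:
                    continue
                v = iou(box, gt)
                if v > best_iou:
                    best_j, best_iou = j, v
            # IoU >= t counts as correct (inclusive); a zero-overlap pair
            # never matches even at threshold 0.
            correct = best_j >= 0 and best_iou > 0 and best_iou >= iou_threshold
            if correct:
                taken[best_j] = True
            flags.append((float(score), correct))
        out[image_id] = flags
    return out


def _detection_ap(
    scores: np.ndarray, correct: np.ndarray, n_ground_truth: int
) -> float:
    """Detection AP: recall measured against the ground-truth count."""
    if n_ground_truth == 0:
        raise ValueError("detection AP undefined with no ground-truth boxes")
    if scores.size == 0:
        return 0.0
    thresholds = np.concatenate([np.unique(scores)[::-1], [-np.inf]])
    above = scores[None, :] > thresholds[:, None]
    tp = (above & correct[None, :]).sum(axis=1)
    npred = above.sum(axis=1)
    recall = tp / n_ground_truth
    precision = np.where(npred > 0, tp / np.maximum(npred, 1), 1.0)
    return float(np.trapezoid(precision, recall))


def map_at(
    pred_set: ScoredPredictionSet,
    thresholds: Sequence[float] = (0.5, 0.75),
    include_coco_range: bool = True,
) -> dict[str, float]:
    """mAP of class-pooled detections at fixed IoU thresholds.

    All predictions are treated as a single "lesion" class and pooled over
    images.  Returns a mapping with one entry per requested threshold
    (``"mAP@0.5"`` etc.) plus, when ``include_coco_range``,
    ``"mAP@[0.5,0.95]"``: the mean AP over thresholds 0.50, 0.55, ..., 0.95.
    """
    n_gt = pred_set.n_ground_truth()
    if n_gt == 0:
        raise ValueError("map_at requires at least one ground-truth box")

    def ap_at(t: float) -> float:
        matched = match_detections(pred_set, t)
        pooled = [sf for flags in matched.values() for sf in flags]
        scores = np.array([s for s, _ in pooled], dtype=float)
        correct = np.array([c for _, c in pooled], dtype=bool)
        return _detection_ap(scores, correct, n_gt)

    report = {f"mAP@{t:g}": ap_at(t) for t in thresholds}
    if include_coco_range:
        report["mAP@[0.5,0.95]"] = float(
            np.mean([ap_at(t) for t in COCO_THRESHOLD_RANGE])
        )
    return report


@dataclass
class RecallIoUSummary:
    recall_iou_gt0: float
    median_iou: float | None
    q1_iou: float | None
    q3_iou: float | None
    n_predictions: int = 0
    n_ground_truth: int = 0


def recall_and_iou_summary(
    pred_set: ScoredPredictionSet, per: str = "predictions"
) -> RecallIoUSummary:
    """Recall at IoU > 0 and the IoU distribution summary.

    Recall counts ground-truth boxes overlapped (strictly positive IoU) by
    at least one prediction in the same image.  The IoU summary is the
    median and quartiles of best-match IoU, by default over predictions
    (zero-overlap predictions contribute 0); ``per="ground_truth"`` summarises
    best IoU per ground-truth box instead.  With no predictions the summary
    is signalled as undefined (``None``).
    """
    if per not in ("predictions", "ground_truth"):
        raise ValueError("per must be 'predictions' or 'ground_truth'")
    n_gt = pred_set.n_ground_truth()
    if n_gt == 0:
        raise ValueError("needs at least one ground-truth box")

    hit = 0
    best_ious: list[float] = []
    for image_id, gts in pred_set.ground_truth.items():
        preds = [b for b, _ in pred_set.predictions.get(image_id, [])]
        for gt in gts:
            overlaps = [iou(p, gt) for p in preds]
            if overlaps and max(overlaps) > 0:
                hit += 1
            if per == "ground_truth":
                best_ious.append(max(overlaps) if overlaps else 0.0)
        if per == "predictions":
            for p in preds:
                overlaps = [iou(p, gt) for gt in gts]
                best_ious.append(max(overlaps) if overlaps else 0.0)

    n_pred = sum(len(v) for v in pred_set.predictions.values())
    if (per == "predictions" and n_pred == 0) or not best_ious:
        return RecallIoUSummary(hit / n_gt, None, None, None, n_pred, n_gt)
    q1, med, q3 = np.percentile(best_ious, [25, 50, 75])  # linear interpolation
    return RecallIoUSummary(
        hit / n_gt, float(med), float(q1), float(q3), n_pred, n_gt
    )
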