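"""Metric suite tests against independent brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

from lesionkit.metrics import (
    ScoredPredictionSet,
    average_precision,
    iou,
    map_at,
    match_detections,
    recall_and_iou_summary,
    roc_auc,
)
from lesionkit.taxonomy import RoiBox


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def concordance_auc(scores, labels):
    """Pairwise concordance probability, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def enumeration_ap(scores, labels):
    """Trapezoid PR area by explicit threshold enumeration.

    Thresholds are the unique observed scores plus one below the minimum;
    TPR/PPV computed by direct counting with strict exceedance, precision
    anchored at 1 where no prediction clears the threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    thresholds = sorted(set(scores), reverse=True) + [-np.inf]
    points = []
    n_pos = labels.sum()
    for t in thresholds:
        sel = scores > t
        tp = int((labels[sel] == 1).sum())
        tpr = tp / n_pos
        ppv = tp / sel.sum() if sel.sum() else 1.0
        points.append((tpr, ppv))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(points, points[1:]):
        area += (r1 - r0) * (p1 + p0) / 2.0
    return area


def rasterized_iou(a: RoiBox, b: RoiBox, resolution: int = 1):
    """Pixel-counting IoU for integer-coordinate boxes."""
    ax0, ay0, ax1, ay1 = (int(v) for v in a.corners())
    bx0, by0, bx1, by1 = (int(v) for v in b.corners())
    w = max(ax1, bx1) + 1
    h = max(ay1, by1) + 1
    ga = np.zeros((h, w), bool)
    gb = np.zeros((h, w), bool)
    ga[ay0:ay1, ax0:ax1] = True
    gb[by0:by1, bx0:bx1] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union


def _random_instance(rng, allow_ties=True):
    n = int(rng.integers(4, 50))
    scores = rng.random(n)
    if allow_ties and rng.random() < 0.5:
        scores = np.round(scores, 1)  # force ties
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[0] = 1
    if labels.sum() == n:
        labels[-1] = 0
    return scores, labels


# ---------------------------------------------------------------------------
# roc_auc / average_precision
# ---------------------------------------------------------------------------


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert roc_auc([0.9, 0.8, 0.3, 0.2], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_concordance_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            scores, labels = _random_instance(rng)
            assert roc_auc(scores, labels) == pytest.approx(
                concordance_auc(scores, labels), abs=1e-12
            )

    def test_null_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.random(10000)
        labels = rng.integers(0, 2, 10000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert average_precision([0.9, 0.8, 0.3, 0.2], [1, 1, 0, 0]) == 1.0

    def test_single_positive_prediction(self):
        assert average_precision([0.7], [1]) == 1.0

    def test_no_positive_raises(self):
        with pytest.raises(ValueError):
            average_precision([0.7, 0.2], [0, 0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            scores, labels = _random_instance(rng)
            assert average_precision(scores, labels) == pytest.approx(
                enumeration_ap(scores, labels), abs=1e-12
            )


# ---------------------------------------------------------------------------
# IoU
# ---------------------------------------------------------------------------


class TestIou:
    def test_identical_boxes(self):
        a = RoiBox(5, 5, 4, 6)
        assert iou(a, a) == 1.0

    def test_disjoint_boxes(self):
        assert iou(RoiBox(2, 2, 2, 2), RoiBox(10, 10, 2, 2)) == 0.0

    def test_offset_two_by_two(self):
        # 2x2 boxes offset horizontally by 1: overlap 2, union 6
        a = RoiBox(1, 1, 2, 2)
        b = RoiBox(2, 1, 2, 2)
        assert iou(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_raster_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            x0, y0 = rng.integers(0, 20, 2)
            w, h = rng.integers(1, 15, 2)
            a = RoiBox.from_corners(x0, y0, x0 + w, y0 + h)
            x0, y0 = rng.integers(0, 20, 2)
            w, h = rng.integers(1, 15, 2)
            b = RoiBox.from_corners(x0, y0, x0 + w, y0 + h)
            assert iou(a, b) == iou(b, a)
            assert iou(a, b) == pytest.approx(rasterized_iou(a, b), abs=1e-12)

    def test_monotone_decrease_under_translation(self):
        a = RoiBox(10, 10, 6, 6)
        values = [iou(a, RoiBox(10 + d, 10, 6, 6)) for d in range(7)]
        assert all(x >= y for x, y in zip(values, values[1:]))
        assert values[-1] == 0.0

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            RoiBox(1, 1, 0, 2)


# ---------------------------------------------------------------------------
# matching / mAP
# ---------------------------------------------------------------------------


def _pred_set(preds, gts):
    return ScoredPredictionSet({"im": preds}, {"im": gts})


class TestMatching:
    def test_one_to_one_higher_score_wins(self):
        gt = [RoiBox(5, 5, 4, 4)]
        preds = [(RoiBox(5, 5, 4, 4), 0.9), (RoiBox(5.5, 5, 4, 4), 0.8)]
        flags = match_detections(_pred_set(preds, gt), 0.5)["im"]
        assert flags == [(0.9, True), (0.8, False)]

    def test_iou_exactly_at_threshold_is_correct(self):
        # IoU(a,b) = 1/3 exactly
        gt = [RoiBox(1, 1, 2, 2)]
        preds = [(RoiBox(2, 1, 2, 2), 0.7)]
        flags = match_detections(_pred_set(preds, gt), 1 / 3)["im"]
        assert flags == [(0.7, True)]

    def test_no_predictions(self):
        flags = match_detections(_pred_set([], [RoiBox(1, 1, 2, 2)]), 0.5)
        assert flags["im"] == []

    def test_prediction_for_unknown_image_rejected(self):
        with pytest.raises(ValueError):
            ScoredPredictionSet(
                {"other": [(RoiBox(1, 1, 2, 2), 0.5)]}, {"im": [RoiBox(1, 1, 2, 2)]}
            )


def brute_force_map(preds, gts, threshold):
    """Independent mAP oracle: greedy matching + enumeration AP with
    recall measured against the ground-truth count."""
    order = sorted(range(len(preds)), key=lambda i: -preds[i][1])
    taken = set()
    flags = []
    for i in order:
        box, score = preds[i]
        cands = [
            (iou(box, g), j)
            for j, g in enumerate(gts)
            if j not in taken and iou(box, g) > 0
        ]
        best = max(cands, default=None)
        if best and best[0] >= threshold:
            taken.add(best[1])
            flags.append((score, 1))
        else:
            flags.append((score, 0))
    scores = np.array([s for s, _ in flags])
    correct = np.array([c for _, c in flags])
    thresholds = sorted(set(scores), reverse=True) + [-np.inf]
    points = []
    for t in thresholds:
        sel = scores > t
        tp = int(correct[sel].sum())
        points.append(
            (tp / len(gts), tp / sel.sum() if sel.sum() else 1.0)
        )
    return sum(
        (r1 - r0) * (p1 + p0) / 2 for (r0, p0), (r1, p1) in zip(points, points[1:])
    )


class TestMapAt:
    def test_perfect_detection(self):
        gts = [RoiBox(5, 5, 4, 4), RoiBox(20, 20, 6, 6)]
        preds = [(g, s) for g, s in zip(gts, (0.9, 0.8))]
        report = map_at(_pred_set(preds, gts))
        assert report["mAP@0.5"] == 1.0
        assert report["mAP@0.75"] == 1.0
        assert report["mAP@[0.5,0.95]"] == 1.0

    def test_all_disjoint(self):
        gts = [RoiBox(5, 5, 4, 4)]
        preds = [(RoiBox(30, 30, 4, 4), 0.9)]
        report = map_at(_pred_set(preds, gts))
        assert report["mAP@0.5"] == 0.0

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            gts = [
                RoiBox(rng.uniform(5, 40), rng.uniform(5, 40), 6, 6)
                for _ in range(3)
            ]
            preds = [
                (
                    RoiBox(
                        g.x_center + rng.normal(0, 2),
                        g.y_center + rng.normal(0, 2),
                        6,
                        6,
                    ),
                    rng.random(),
                )
                for g in gts
            ] + [(RoiBox(rng.uniform(5, 40), rng.uniform(5, 40), 6, 6), rng.random())]
            report = map_at(_pred_set(preds, gts))
            assert report["mAP@0.75"] <= report["mAP@0.5"] + 1e-12

    def test_mixed_scene_matches_brute_force_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            gts = [
                RoiBox(rng.uniform(4, 40), rng.uniform(4, 40), rng.uniform(3, 8), rng.uniform(3, 8))
                for _ in range(int(rng.integers(1, 4)))
            ]
            preds = [
                (
                    RoiBox(
                        rng.uniform(4, 40), rng.uniform(4, 40),
                        rng.uniform(3, 8), rng.uniform(3, 8),
                    ),
                    round(rng.random(), 2),
                )
                for _ in range(int(rng.integers(0, 6)))
            ]
            report = map_at(_pred_set(preds, gts), thresholds=(0.5,), include_coco_range=False)
            assert report["mAP@0.5"] == pytest.approx(
                brute_force_map(preds, gts, 0.5), abs=1e-12
            )

    def test_no_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            map_at(ScoredPredictionSet({}, {"im": []}))

    def test_invariant_to_image_relabeling_and_order(self):
        rng = np.random.default_rng(5)
        gts = {
            "a": [RoiBox(10, 10, 6, 6)],
            "b": [RoiBox(8, 8, 5, 5), RoiBox(30, 30, 6, 6)],
        }
        preds = {
            "a": [(RoiBox(10.5, 10, 6, 6), 0.9)],
            "b": [(RoiBox(8, 8, 5, 5), 0.7), (RoiBox(29, 30, 6, 6), 0.4)],
        }
        base = map_at(ScoredPredictionSet(preds, gts))
        renamed = map_at(
            ScoredPredictionSet(
                {"x": preds["a"], "y": preds["b"]},
                {"x": gts["a"], "y": gts["b"]},
            )
        )
        shuffled = map_at(
            ScoredPredictionSet(
                {"a": preds["a"], "b": preds["b"][::-1]}, gts
            )
        )
        assert base == renamed == shuffled


class TestRecallIoUSummary:
    def test_every_gt_overlapped(self):
        gts = [RoiBox(5, 5, 4, 4), RoiBox(20, 20, 6, 6)]
        preds = [(RoiBox(5.5, 5, 4, 4), 0.9), (RoiBox(19, 20, 6, 6), 0.8)]
        summary = recall_and_iou_summary(_pred_set(preds, gts))
        assert summary.recall_iou_gt0 == 1.0

    def test_no_predictions_signals_undefined_summary(self):
        summary = recall_and_iou_summary(_pred_set([], [RoiBox(5, 5, 4, 4)]))
        assert summary.recall_iou_gt0 == 0.0
        assert summary.median_iou is None
        assert summary.q1_iou is None

    def test_hand_enumerated_quartiles(self):
        # three predictions with best-match IoU {0.2, 0.5, 0.8}:
        # median 0.5; linear-interpolation quartiles 0.35 / 0.65
        gt = RoiBox.from_corners(0, 0, 10, 10)

        def box_with_iou(target):
            # shrink a corner-anchored box until IoU hits the target
            from scipy.optimize import brentq

            def f(s):
                return iou(RoiBox.from_corners(0, 0, 10 * s, 10), gt) - target

            s = brentq(f, 0.01, 1.0)
            return RoiBox.from_corners(0, 0, 10 * s, 10)

        preds = [(box_with_iou(v), 0.5 + i * 0.1) for i, v in enumerate((0.2, 0.5, 0.8))]
        summary = recall_and_iou_summary(
            ScoredPredictionSet({"im": preds}, {"im": [gt]})
        )
        assert summary.median_iou == pytest.approx(0.5, abs=1e-9)
        assert summary.q1_iou == pytest.approx(0.35, abs=1e-9)
        assert summary.q3_iou == pytest.approx(0.65, abs=1e-9)

    def test_per_ground_truth_variant(self):
        gts = [RoiBox(5, 5, 4, 4), RoiBox(30, 30, 4, 4)]
        preds = [(RoiBox(5, 5, 4, 4), 0.9)]
        summary = recall_and_iou_summary(_pred_set(preds, gts), per="ground_truth")
        assert summary.recall_iou_gt0 == 0.5
        assert summary.median_iou == pytest.approx(0.5)  # {1.0, 0.0}
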