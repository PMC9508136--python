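"""Lesion identification: a region-proposal detector at three label granularities.

The detector follows the two-part structure of region-proposal detection:

1. *Proposal stage.*  The image is resized to a fixed working resolution and
   a color-contrast map (distance from the estimated background skin color)
   is computed.  The map is thresholded after Gaussian smoothing at several
   scales of a pyramid — the multi-scale analogue of feature-pyramid
   detection, letting lesions of widely varying lesion-to-image ratios
   surface as connected components.  Component tight boxes are the region
   proposals.  Proposal scales are derived from the ground-truth box sizes
   seen at fit time (data-driven anchors).

2. *Classification stage.*  Each proposal crop is scored by a seeded
   convolutional network (the tiny 4-block backbone, global average pooling,
   softmax head) over C foreground classes plus background, trained with SGD
   (momentum 0.9, weight decay 1e-4, step learning-rate decay) on proposals
   labelled by IoU against the annotations, up to ``proposals_per_image``
   sampled regions per image.

Granularity C is 1 (*one-class*: any lesion), 2 (*malignancy*:
malignant/benign) or 8 (*sub-type*: the full taxonomy).  Detection keeps
proposals whose foreground score ``1 - p(background)`` clears
``score_threshold``, applies greedy non-maximum suppression, and returns
boxes sorted by descending score with per-class probability vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .classifier import extract_crop
from .metrics import iou
from .nn import SGDTrainer, TinyConvNet
from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedImage,
    LesionTaxonomy,
    LesionType,
    RoiBox,
)

logger = logging.getLogger(__name__)

__all__ = ["Granularity", "DetectionResult", "LesionDetector", "nms"]

_PROB_EPS = 1e-7
_POS_IOU = 0.5
_NEG_IOU = 0.3


@dataclass(frozen=True)
class Granularity:
    """Detector label granularity: C = 1, 2 or 8 classes."""

    mode: str
    class_names: tuple[str, ...]

    _MODES = ("one_class", "malignancy", "sub_type")

    @classmethod
    def create(
        cls, mode: str, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY
    ) -> "Granularity":
        if mode == "one_class":
            names: tuple[str, ...] = ("lesion",)
        elif mode == "malignancy":
            names = ("malignant", "benign")
        elif mode == "sub_type":
            names = tuple(t.name for t in taxonomy.types)
        else:
            raise ValueError(
                f"unknown granularity {mode!r}; choose from {cls._MODES}"
            )
        return cls(mode=mode, class_names=names)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def class_index(
        self, lesion_type: LesionType, taxonomy: LesionTaxonomy
    ) -> int:
        if self.mode == "one_class":
            return 0
        if self.mode == "malignancy":
            return 0 if taxonomy.is_malignant(lesion_type) else 1
        return self.class_names.index(lesion_type.name)


@dataclass
class DetectionResult:
    """Predicted boxes with per-class probabilities and confidence scores.

    Boxes are clipped to the image and ordered by descending score;
    ``class_probs`` rows live in (0,1)^C.
    """

    boxes: list[RoiBox]
    class_probs: np.ndarray  # (m_hat, C)
    scores: np.ndarray  # (m_hat,)
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.class_probs = np.atleast_2d(np.asarray(self.class_probs, float))
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.boxes) == 0:
            n_classes = (
                self.class_probs.shape[-1]
                if self.class_probs.ndim >= 2 and self.class_probs.shape[-1] > 0
                else max(1, len(self.class_names))
            )
            self.class_probs = self.class_probs.reshape(0, n_classes)
        if not (
            len(self.boxes) == self.class_probs.shape[0] == self.scores.shape[0]
        ):
            raise ValueError("boxes, class_probs and scores lengths disagree")
        if self.scores.size and np.any(np.diff(self.scores) > 1e-12):
            raise ValueError("detections must be sorted by descending score")

    @property
    def m_hat(self) -> int:
        return len(self.boxes)

    def malignancy_probs(self, taxonomy: LesionTaxonomy) -> np.ndarray:
        """Per-box malignancy probability from the class-probability vector.

        For the malignancy granularity this is the 'malignant' entry; for
        sub-type, the sum of class probabilities over the malignant set
        (the measure-consistent reduction); the one-class detector carries
        no malignancy information and raises.
        """
        if self.class_names == ("malignant", "benign"):
            return self.class_probs[:, 0]
        if set(self.class_names) == {t.name for t in taxonomy.types}:
            idx = [
                i
                for i, name in enumerate(self.class_names)
                if taxonomy.is_malignant(LesionType.from_code(name))
            ]
            return self.class_probs[:, idx].sum(axis=1)
        raise ValueError(
            "one-class detections carry no malignancy information; use the "
            "two-stage strategy with a malignancy classifier"
        )


def _overlap_over_min(a: RoiBox, b: RoiBox) -> float:
    ax0, ay0, ax1, ay1 = a.corners()
    bx0, by0, bx1, by1 = b.corners()
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    return iw * ih / min(a.area, b.area)


def nms(
    boxes: Sequence[RoiBox],
    scores: np.ndarray,
    iou_threshold: float,
    containment_threshold: float | None = 0.75,
) -> list[int]:
    """Greedy non-maximum suppression; returns kept indices, score-descending.

    Besides the usual IoU criterion, a box whose overlap with an
    already-kept box exceeds ``containment_threshold`` of the smaller box's
    area is suppressed: nested duplicates (e.g. a lesion's darker core
    proposed inside the full lesion) have low IoU but near-total containment.
    """
    order = list(np.argsort(-np.asarray(scores)))
    keep: list[int] = []
    while order:
        i = order.pop(0)
        keep.append(i)
        kept = []
        for j in order:
            if iou(boxes[i], boxes[j]) > iou_threshold:
                continue
            if (
                containment_threshold is not None
                and _overlap_over_min(boxes[i], boxes[j]) > containment_threshold
            ):
                continue
            kept.append(j)
        order = kept
    return keep


_FIELD_LUMINANCE_MIN = 35.0  # below this a pixel is outside the dermoscopy field


def _background_distance(pixels: np.ndarray) -> np.ndarray:
    """Color distance from the estimated background skin color.

    Near-black pixels (the circular vignette outside a dermoscopy field)
    are excluded from the background estimate and zeroed in the map, so the
    field border does not masquerade as a giant lesion.
    """
    x = pixels.astype(np.float64)
    luminance = x @ np.array([0.299, 0.587, 0.114])
    in_field = luminance >= _FIELD_LUMINANCE_MIN
    flat = x.reshape(-1, 3)
    sel = in_field.reshape(-1)
    bg = np.median(flat[sel] if sel.any() else flat, axis=0)
    dist = np.sqrt(((x - bg) ** 2).sum(axis=-1))
    dist[~in_field] = 0.0
    return dist


def _propose(
    pixels: np.ndarray,
    sigmas: Sequence[float],
    min_area: float = 9.0,
    max_area_fraction: float = 0.9,
    dedup_iou: float = 0.9,
) -> list[RoiBox]:
    """Multi-scale contrast-map proposals: smooth, threshold, tight boxes."""
    h, w = pixels.shape[:2]
    dist = _background_distance(pixels)
    proposals: list[RoiBox] = []
    for sigma in sigmas:
        smoothed = gaussian(dist, sigma=sigma, preserve_range=True)
        spread = smoothed.max() - smoothed.min()
        if spread < 1e-6:
            continue
        try:
            thr = threshold_otsu(smoothed)
        except ValueError:
            continue
        # Otsu on a near-uniform map fires on noise; require real contrast.
        if spread < 12.0:
            continue
        # two threshold levels per scale: the Otsu split plus a lower level
        # that surfaces small/faint lesions overshadowed by strong ones
        for level in (thr, 0.55 * thr):
            mask = smoothed > level
            for region in regionprops(cc_label(mask)):
                if region.area < min_area:
                    continue
                if region.area > max_area_fraction * h * w:
                    continue
                r0, c0, r1, c1 = region.bbox
                if r1 - r0 < 2 or c1 - c0 < 2:
                    continue
                cand = RoiBox.from_corners(
                    float(c0), float(r0), float(c1), float(r1)
                )
                if all(iou(cand, p) < dedup_iou for p in proposals):
                    proposals.append(cand)
                # refine: re-threshold the raw contrast map inside the
                # component window; splits merged neighbouring lesions and
                # tightens boxes inflated by smoothing
                pad = 2
                wr0, wc0 = max(0, r0 - pad), max(0, c0 - pad)
                wr1, wc1 = min(h, r1 + pad), min(w, c1 + pad)
                window = dist[wr0:wr1, wc0:wc1]
                if window.max() - window.min() < 12.0:
                    continue
                try:
                    wthr = threshold_otsu(window)
                except ValueError:
                    continue
                for sub in regionprops(cc_label(window > wthr)):
                    if sub.area < min_area:
                        continue
                    s0, t0, s1, t1 = sub.bbox
                    if s1 - s0 < 2 or t1 - t0 < 2:
                        continue
                    cand = RoiBox.from_corners(
                        float(wc0 + t0),
                        float(wr0 + s0),
                        float(wc0 + t1),
                        float(wr0 + s1),
                    )
                    if all(iou(cand, p) < dedup_iou for p in proposals):
                        proposals.append(cand)
    return proposals


class LesionDetector(BaseEstimator):
    """Region-proposal lesion detector with configurable label granularity.

    The printed full-scale recipe (25 epochs, 512 sampled proposals per
    image, initial learning rate 0.001 with 10x step decay) is the default;
    the step-decay milestones keep their fractional positions when the run
    has fewer total steps.  ``work_side`` is the internal working resolution
    (multi-scale resize), which also makes detection approximately invariant
    to input rescaling.
    """

    def __init__(
        self,
        granularity: str = "one_class",
        backbone_depth: str = "tiny",
        fpn_levels: int = 3,
        epochs: int = 25,
        proposals_per_image: int = 512,
        lr_init: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        score_threshold: float = 0.5,
        nms_iou: float = 0.5,
        input_side: int = 32,
        work_side: int = 128,
        batch_size: int = 64,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        seed: int = 0,
    ):
        self.granularity = granularity
        self.backbone_depth = backbone_depth
        self.fpn_levels = fpn_levels
        self.epochs = epochs
        self.proposals_per_image = proposals_per_image
        self.lr_init = lr_init
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.score_threshold = score_threshold
        self.nms_iou = nms_iou
        self.input_side = input_side
        self.work_side = work_side
        self.batch_size = batch_size
        self.channels = channels
        self.seed = seed

    # -- internals -------------------------------------------------------

    def _check_config(self) -> None:
        if self.backbone_depth == "resnet50":
            raise NotImplementedError(
                "the resnet50 backbone requires a pretrained deep-learning "
                "framework; use backbone_depth='tiny'"
            )
        if self.backbone_depth != "tiny":
            raise ValueError(f"unknown backbone_depth {self.backbone_depth!r}")
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must be in (0,1)")
        if not 0.0 < self.nms_iou < 1.0:
            raise ValueError("nms_iou must be in (0,1)")
        if self.lr_init <= 0:
            raise ValueError("lr_init must be positive")

    def _to_working(self, pixels: np.ndarray) -> tuple[np.ndarray, float]:
        h, w = pixels.shape[:2]
        if min(h, w) < 16:
            logger.warning(
                "image smaller than the minimum input side; rescaling up"
            )
        scale = self.work_side / max(h, w)
        nh, nw = max(16, round(h * scale)), max(16, round(w * scale))
        work = _sk_resize(
            pixels.astype(np.float64),
            (nh, nw, 3),
            order=1,
            mode="edge",
            anti_aliasing=True,
            preserve_range=True,
        )
        return np.clip(work, 0, 255).astype(np.uint8), scale

    def _sigmas(self) -> list[float]:
        lo, hi = self.anchor_fraction_range_
        lo_s = max(1.0, 0.75 * lo * self.work_side / 4.0)
        hi_s = max(lo_s + 0.5, 1.25 * hi * self.work_side / 4.0)
        n = max(2, int(self.fpn_levels))
        return list(np.geomspace(lo_s, hi_s, n))

    def _crop(self, work: np.ndarray, box: RoiBox) -> np.ndarray:
        return extract_crop(work, box, self.input_side, 0.1)

    # -- estimator API ---------------------------------------------------

    def fit(
        self,
        images: Sequence[AnnotatedImage],
        taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
    ) -> "LesionDetector":
        self._check_config()
        if not images:
            raise ValueError("empty training set")
        self.taxonomy_ = taxonomy
        self.taxonomy_hash_ = taxonomy.hash_key()
        self.granularity_ = Granularity.create(self.granularity, taxonomy)
        C = self.granularity_.n_classes
        self.background_index_ = C

        # data-driven anchors: lesion side as a fraction of the image side
        fracs = []
        for image in images:
            side = max(image.width, image.height)
            for box, _ in image.rois:
                fracs.append(max(box.width, box.height) / side)
        self.anchor_fraction_range_ = (
            float(np.percentile(fracs, 5)),
            float(np.percentile(fracs, 95)),
        )

        rng = np.random.default_rng(self.seed)
        crops, labels = [], []
        n_excluded = 0
        for image in images:
            work, scale = self._to_working(image.pixels)
            wh, ww = work.shape[:2]
            gt = []
            for box, lesion_type in image.rois:
                scaled = box.scaled(scale)
                try:
                    scaled = scaled.clipped(ww, wh)
                except ValueError:
                    continue
                gt.append((scaled, lesion_type))
            if not gt:
                n_excluded += 1
                logger.warning(
                    "image %s excluded: all ROIs collapsed to zero area at "
                    "the working resolution",
                    image.image_id,
                )
                continue

            candidates = list(_propose(work, self._sigmas()))
            # jittered copies of the annotations enrich the positives
            for box, _ in gt:
                for _ in range(4):
                    f = rng.uniform(0.9, 1.15)
                    jb = RoiBox(
                        box.x_center + rng.uniform(-0.1, 0.1) * box.width,
                        box.y_center + rng.uniform(-0.1, 0.1) * box.height,
                        box.width * f,
                        box.height * f,
                    )
                    try:
                        candidates.append(jb.clipped(ww, wh, warn=False))
                    except ValueError:
                        pass
            # random background boxes at anchor scales
            lo, hi = self.anchor_fraction_range_
            for _ in range(12):
                f = rng.uniform(lo, hi)
                bw = max(4.0, f * max(ww, wh))
                if bw >= min(ww, wh):
                    continue
                cx = rng.uniform(bw / 2, ww - bw / 2)
                cy = rng.uniform(bw / 2, wh - bw / 2)
                candidates.append(RoiBox(cx, cy, bw, bw))

            pos, neg = [], []
            for cand in candidates:
                best_iou, best_type = 0.0, None
                for box, lesion_type in gt:
                    v = iou(cand, box)
                    if v > best_iou:
                        best_iou, best_type = v, lesion_type
                if best_iou >= _POS_IOU:
                    pos.append(
                        (cand, self.granularity_.class_index(best_type, taxonomy))
                    )
                elif best_iou < _NEG_IOU:
                    neg.append((cand, self.background_index_))
            # sample up to proposals_per_image regions, ~1:3 positives:negatives
            n_pos = min(len(pos), max(1, self.proposals_per_image // 4))
            n_neg = min(len(neg), self.proposals_per_image - n_pos)
            take_pos = [pos[i] for i in rng.permutation(len(pos))[:n_pos]]
            take_neg = [neg[i] for i in rng.permutation(len(neg))[:n_neg]]
            for box, cls in take_pos + take_neg:
                try:
                    crops.append(self._crop(work, box))
                except ValueError:
                    continue
                labels.append(cls)

        if not crops:
            raise ValueError("no usable training regions were produced")
        X = np.stack(crops)
        y = np.array(labels, dtype=int)
        self.net_ = TinyConvNet(n_out=C + 1, channels=self.channels, seed=self.seed)
        trainer = SGDTrainer(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_init=self.lr_init,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            schedule="step",
            seed=self.seed + 1,
        )
        self.loss_history_ = trainer.train(self.net_, X, y)
        self.n_train_regions_ = int(X.shape[0])
        self.n_excluded_images_ = n_excluded
        logger.info(
            "detector trained on %d regions from %d images (%d excluded)",
            X.shape[0],
            len(images),
            n_excluded,
        )
        return self

    def detect(self, image: AnnotatedImage | np.ndarray) -> DetectionResult:
        """Detect lesions in one RGB image."""
        check_is_fitted(self, "net_")
        pixels = image.pixels if isinstance(image, AnnotatedImage) else image
        pixels = np.asarray(pixels)
        work, scale = self._to_working(pixels)
        wh, ww = work.shape[:2]
        proposals = _propose(work, self._sigmas())
        if not proposals:
            return DetectionResult(
                [], np.zeros((0, self.granularity_.n_classes)), np.zeros(0),
                self.granularity_.class_names,
            )
        X = np.stack([self._crop(work, b) for b in proposals])
        probs = self.net_.predict_proba(X)  # (N, C+1)
        # detection confidence follows class-wise detection semantics: the
        # predicted (best) foreground class against background,
        # p_c / (p_c + p_bg).  Spreading probability mass over many granular
        # classes lowers confidence; a one-class head is unaffected.
        best_fg = probs[:, : self.granularity_.n_classes].max(axis=1)
        p_bg = probs[:, self.background_index_]
        scores = best_fg / (best_fg + p_bg)
        keep = [i for i in range(len(proposals)) if scores[i] >= self.score_threshold]
        if not keep:
            return DetectionResult(
                [], np.zeros((0, self.granularity_.n_classes)), np.zeros(0),
                self.granularity_.class_names,
            )
        boxes = [proposals[i] for i in keep]
        kept_scores = scores[keep]
        order = nms(boxes, kept_scores, self.nms_iou)
        boxes = [boxes[i] for i in order]
        kept_scores = kept_scores[order]
        fg = probs[np.array(keep)[order], : self.granularity_.n_classes]
        fg = np.clip(fg, _PROB_EPS, None)
        fg = fg / fg.sum(axis=1, keepdims=True)
        fg = np.clip(fg, _PROB_EPS, 1.0 - _PROB_EPS)

        h, w = pixels.shape[:2]
        out_boxes = []
        for b in boxes:
            out_boxes.append(b.scaled(1.0 / scale).clipped(w, h, warn=False))
        return DetectionResult(
            out_boxes,
            fg,
            np.clip(kept_scores, _PROB_EPS, 1.0 - _PROB_EPS),
            self.granularity_.class_names,
        )

    def predict(self, images) -> list[DetectionResult]:
        if isinstance(images, (AnnotatedImage, np.ndarray)):
            return [self.detect(images)]
        return [self.detect(im) for im in images]

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "LesionDetector":
        return joblib.load(path)
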