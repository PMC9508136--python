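"""Image-level malignancy probability via multiple-instance aggregation.

An image-level screening score ``p(y=1|X)`` is produced by one of three
strategies:

* ``direct`` — a whole-image convolutional classifier.
* ``two_stage`` — detect lesions (any granularity, typically one-class),
  score each detected box with the crop-level malignancy classifier, then
  aggregate the per-box probabilities.
* ``one_step`` — a malignancy- or sub-type-granularity detector whose
  per-box class probabilities are reduced to malignancy probabilities
  (the 'malignant' entry for C=2; the sum over the malignant set for C=8)
  and aggregated directly.

Aggregators are permutation-invariant functions of the multiset of per-box
probabilities: the average, the maximum, and noisy-OR.  Noisy-OR is the
probabilistic union of independent per-region malignancy events,
``1 - prod(1 - p_i)``.  A variant ``noisy_or_as_printed`` computes
``1 - prod(p_i)`` instead; note that this form *decreases* as individual
malignancy probabilities increase, which makes it degenerate for its stated
purpose — it is retained only for comparison and is not the default.

Images in which the detector finds no boxes fall back to a configurable
behavior: a fixed prior probability (default 0.0) or, when a direct model is
attached, the direct-path probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .classifier import MalignancyCropClassifier, full_image_box
from .detector import LesionDetector
from .taxonomy import DEFAULT_TAXONOMY, AnnotatedImage, LesionTaxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "AGGREGATORS",
    "aggregate",
    "StrategySpec",
    "ImageMalignancyScorer",
]

AGGREGATORS = ("average", "maximum", "noisy_or", "noisy_or_as_printed")


def aggregate(probs: Sequence[float], aggregator: str) -> float:
    """Aggregate a non-empty multiset of per-box probabilities.

    Permutation-invariant by construction.  Raises on an empty list: the
    zero-detection fallback is the caller's responsibility.
    """
    p = np.asarray(list(probs), dtype=float)
    if p.size == 0:
        raise ValueError(
            "cannot aggregate an empty probability set; apply the "
            "zero-detection fallback first"
        )
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("probabilities must lie strictly in (0, 1)")
    # sort first so reductions are bit-exact under permutation of the input
    p = np.sort(p)
    if aggregator == "average":
        return float(p.mean())
    if aggregator == "maximum":
        return float(p.max())
    if aggregator == "noisy_or":
        return float(1.0 - np.prod(1.0 - p))
    if aggregator == "noisy_or_as_printed":
        return float(1.0 - np.prod(p))
    raise ValueError(f"unknown aggregator {aggregator!r}; choose from {AGGREGATORS}")


@dataclass(frozen=True)
class StrategySpec:
    """Which image-level strategy to run and how to aggregate.

    ``fallback_prior`` is the probability reported for zero-detection
    images when no direct model is attached.
    """

    strategy: str = "two_stage"  # direct | two_stage | one_step
    aggregator: str = "maximum"
    fallback: str = "prior"  # "prior" | "direct"
    fallback_prior: float = 0.0

    def __post_init__(self) -> None:
        if self.strategy not in ("direct", "two_stage", "one_step"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"unknown aggregator {self.aggregator!r}")
        if self.fallback not in ("prior", "direct"):
            raise ValueError(f"unknown fallback {self.fallback!r}")


@dataclass
class ImageMalignancyScorer:
    """Composes trained models into an image-level malignancy probability.

    Required models depend on the strategy: ``direct`` needs
    ``direct_model`` (a whole-image :class:`MalignancyCropClassifier`);
    ``two_stage`` needs ``detector`` + ``crop_model``; ``one_step`` needs a
    detector trained at malignancy or sub-type granularity.
    """

    spec: StrategySpec = field(default_factory=StrategySpec)
    detector: LesionDetector | None = None
    crop_model: MalignancyCropClassifier | None = None
    direct_model: MalignancyCropClassifier | None = None
    taxonomy: LesionTaxonomy = field(default_factory=lambda: DEFAULT_TAXONOMY)

    def __post_init__(self) -> None:
        s = self.spec.strategy
        if s == "direct" and self.direct_model is None:
            raise ValueError("direct strategy requires direct_model")
        if s == "two_stage" and (self.detector is None or self.crop_model is None):
            raise ValueError("two_stage strategy requires detector and crop_model")
        if s == "one_step":
            if self.detector is None:
                raise ValueError("one_step strategy requires a detector")
            if getattr(self.detector, "granularity", None) == "one_class":
                raise ValueError(
                    "one_step requires a malignancy or sub_type detector; "
                    "one-class boxes carry no malignancy information"
                )
        if self.detector is not None and hasattr(self.detector, "taxonomy_hash_"):
            if self.detector.taxonomy_hash_ != self.taxonomy.hash_key():
                raise ValueError("detector was trained under a different taxonomy")

    # -- scoring ---------------------------------------------------------

    def _direct_probability(self, pixels: np.ndarray) -> float:
        assert self.direct_model is not None
        return self.direct_model.predict_malignancy(pixels, full_image_box(pixels))

    def _fallback(self, pixels: np.ndarray) -> tuple[float, int]:
        logger.info("no detections; applying %s fallback", self.spec.fallback)
        if self.spec.fallback == "direct" and self.direct_model is not None:
            return self._direct_probability(pixels), 0
        return float(self.spec.fallback_prior), 0

    def image_probability(
        self, image: AnnotatedImage | np.ndarray
    ) -> tuple[float, int]:
        """Return ``(probability, m_hat)`` for one image."""
        pixels = image.pixels if isinstance(image, AnnotatedImage) else np.asarray(image)
        if self.spec.strategy == "direct":
            return self._direct_probability(pixels), 0

        assert self.detector is not None
        result = self.detector.detect(pixels)
        if result.m_hat == 0:
            return self._fallback(pixels)

        if self.spec.strategy == "two_stage":
            assert self.crop_model is not None
            probs = [
                self.crop_model.predict_malignancy(pixels, box)
                for box in result.boxes
            ]
        else:  # one_step
            probs = list(result.malignancy_probs(self.taxonomy))
        probs = list(np.clip(probs, 1e-7, 1.0 - 1e-7))
        return aggregate(probs, self.spec.aggregator), result.m_hat

    def predict_proba(self, images: Sequence[AnnotatedImage | np.ndarray]) -> np.ndarray:
        return np.array([self.image_probability(im)[0] for im in images])
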