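"""Crop-level malignancy classifier.

Given a lesion bounding box, the classifier extracts the corresponding image
region (with a small context margin), resizes it to a square input, runs it
through a convolutional feature extractor truncated at its 4th block, global
average pooling and a fully connected sigmoid head, and returns the
probability that the lesion is malignant.  Training is SGD with momentum,
weight decay and a half-period cosine learning-rate schedule, with
resize/rotate data augmentation.
"""

from __future__ import annotations

import math
from typing import Sequence

import joblib
import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .nn import SGDTrainer, TinyConvNet
from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedImage,
    LesionTaxonomy,
    RoiBox,
)

__all__ = [
    "extract_crop",
    "crop_dataset",
    "MalignancyCropClassifier",
    "full_image_box",
]

_PROB_EPS = 1e-7


def _resize_uint8(patch: np.ndarray, side: int) -> np.ndarray:
    out = _sk_resize(
        patch.astype(np.float64),
        (side, side, 3),
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def extract_crop(
    pixels: np.ndarray,
    box: RoiBox,
    input_side: int = 224,
    crop_padding_fraction: float = 0.1,
) -> np.ndarray:
    """Extract the (padded, clipped) box region resized to a square crop.

    The box is expanded by ``crop_padding_fraction`` of its width/height on
    each side, clipped to the image, sliced on integer pixel bounds and
    resized (bilinear, anisotropic) to ``input_side x input_side``.
    Deterministic; raises on a zero-area region.
    """
    pixels = np.asarray(pixels)
    h, w = pixels.shape[:2]
    x0, y0, x1, y1 = box.corners()
    px = crop_padding_fraction * box.width
    py = crop_padding_fraction * box.height
    ix0 = max(0, int(math.floor(x0 - px)))
    iy0 = max(0, int(math.floor(y0 - py)))
    ix1 = min(w, int(math.ceil(x1 + px)))
    iy1 = min(h, int(math.ceil(y1 + py)))
    if ix1 <= ix0 or iy1 <= iy0:
        raise ValueError(f"box {box} has zero area within the image")
    return _resize_uint8(pixels[iy0:iy1, ix0:ix1], input_side)


def full_image_box(image: AnnotatedImage | np.ndarray) -> RoiBox:
    """The box covering an entire image (used by the direct strategy)."""
    pixels = image.pixels if isinstance(image, AnnotatedImage) else image
    h, w = pixels.shape[:2]
    return RoiBox(w / 2.0, h / 2.0, float(w), float(h))


def crop_dataset(
    images: Sequence[AnnotatedImage],
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
    input_side: int = 32,
    crop_padding_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """All ROI crops of an annotated set with binary malignancy labels."""
    crops, labels = [], []
    for image in images:
        for box, lesion_type in image.rois:
            crops.append(
                extract_crop(image.pixels, box, input_side, crop_padding_fraction)
            )
            labels.append(int(taxonomy.is_malignant(lesion_type)))
    return np.stack(crops), np.array(labels, dtype=int)


def _augment_batch(
    batch: np.ndarray,
    rng: np.random.Generator,
    rotate: bool,
    rescale: bool,
) -> np.ndarray:
    out = np.empty_like(batch)
    side = batch.shape[1]
    for i, img in enumerate(batch):
        if rotate:
            img = np.rot90(img, k=int(rng.integers(4)), axes=(0, 1))
        if rescale:
            scale = float(rng.uniform(0.85, 1.15))
            if abs(scale - 1.0) > 1e-3:
                if scale > 1.0:  # zoom in: take a centered sub-window
                    inner = max(4, int(round(side / scale)))
                    off = (side - inner) // 2
                    img = _resize_uint8(
                        img[off : off + inner, off : off + inner], side
                    )
                else:  # zoom out: reflect-pad then resize back
                    pad = max(1, int(round(side * (1.0 / scale - 1.0) / 2)))
                    img = _resize_uint8(
                        np.pad(
                            img, ((pad, pad), (pad, pad), (0, 0)), mode="reflect"
                        ),
                        side,
                    )
        out[i] = img
    return out


class MalignancyCropClassifier(BaseEstimator, ClassifierMixin):
    """Convolutional malignancy classifier for lesion crops.

    Parameters largely mirror the training recipe of the full-scale model
    (SGD, momentum 0.9, weight decay 1e-4, cosine schedule); the
    ``tiny`` backbone is a seeded 4-block NumPy conv-net suitable for
    CPU-scale training.  The ``resnet50`` option names the full-fidelity
    architecture and requires a deep-learning framework with pretrained
    weights, which this package does not ship.
    """

    def __init__(
        self,
        backbone_depth: str = "tiny",
        input_side: int = 224,
        epochs: int = 120,
        batch_size: int = 64,
        lr_init: float = 0.01,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        schedule: str = "cosine",
        augment: tuple[str, ...] = ("resize", "rotate"),
        crop_padding_fraction: float = 0.1,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        seed: int = 0,
    ):
        self.backbone_depth = backbone_depth
        self.input_side = input_side
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.schedule = schedule
        self.augment = augment
        self.crop_padding_fraction = crop_padding_fraction
        self.channels = channels
        self.seed = seed

    def _check_config(self) -> None:
        if self.backbone_depth == "resnet50":
            raise NotImplementedError(
                "the resnet50 backbone requires a pretrained deep-learning "
                "framework; use backbone_depth='tiny'"
            )
        if self.backbone_depth != "tiny":
            raise ValueError(f"unknown backbone_depth {self.backbone_depth!r}")
        if self.input_side <= 0 or self.lr_init <= 0:
            raise ValueError("input_side and lr_init must be positive")

    def _as_crop_batch(self, X) -> np.ndarray:
        X = np.asarray(X)
        if X.ndim == 3:
            X = X[None]
        if X.shape[1] != self.input_side or X.shape[2] != self.input_side:
            X = np.stack([_resize_uint8(im, self.input_side) for im in X])
        return X

    def fit(self, X, y) -> "MalignancyCropClassifier":
        """Fit on crops ``X`` (N x H x W x 3 uint8) with binary labels."""
        self._check_config()
        X = self._as_crop_batch(X)
        y = np.asarray(y, dtype=int)
        present = set(np.unique(y))
        for cls, name in ((1, "malignant"), (0, "benign")):
            if cls not in present:
                raise ValueError(
                    f"training set contains no {name} examples; both classes "
                    "are required"
                )
        self.classes_ = np.array([0, 1])
        self.net_ = TinyConvNet(
            n_out=1, channels=self.channels, seed=self.seed
        )
        trainer = SGDTrainer(
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_init=self.lr_init,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            schedule=self.schedule,
            seed=self.seed + 1,
        )
        rotate = "rotate" in self.augment
        rescale = "resize" in self.augment
        augment_fn = (
            (lambda b, rng: _augment_batch(b, rng, rotate, rescale))
            if (rotate or rescale)
            else None
        )
        self.loss_history_ = trainer.train(self.net_, X, y, augment_fn)
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "net_")
        p = self.net_.predict_proba(self._as_crop_batch(X))
        p = np.clip(p, _PROB_EPS, 1.0 - _PROB_EPS)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def predict_malignancy(
        self, pixels: np.ndarray | AnnotatedImage, box: RoiBox
    ) -> float:
        """Malignancy probability (strictly in (0,1)) for one image region."""
        if isinstance(pixels, AnnotatedImage):
            pixels = pixels.pixels
        crop = extract_crop(
            pixels, box, self.input_side, self.crop_padding_fraction
        )
        return float(self.predict_proba(crop[None])[0, 1])

    def crop_features(self, X) -> np.ndarray:
        """Frozen global-average-pooled backbone features for crops."""
        check_is_fitted(self, "net_")
        return self.net_.features(self._as_crop_batch(X))

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MalignancyCropClassifier":
        return joblib.load(path)
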