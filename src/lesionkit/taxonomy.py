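"""Domain types for annotated skin-lesion images.

The data model is a set of annotated images ``{X_n, Z_n, U_n, y_n}``: an RGB
image, a non-empty set of lesion bounding boxes (regions of interest, ROIs),
per-ROI lesion-type labels from an 8-type taxonomy, and a derived image-level
malignancy label.  An image is malignant when at least one of its ROIs carries
a malignant type; the malignant set is {melanoma, basal cell carcinoma,
actinic keratosis/Bowen's disease (including squamous cell carcinoma)}.

Boxes are stored center-based, ``(x_center, y_center, width, height)`` in
continuous 0-based pixel coordinates.  Conversion to half-open corner
intervals happens only inside overlap/area computations (see
:mod:`lesionkit.metrics`).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LesionType",
    "LesionTaxonomy",
    "RoiBox",
    "AnnotatedImage",
    "DatasetLedger",
    "DEFAULT_TAXONOMY",
    "image_label",
    "ledger_totals",
    "merge_ledgers",
    "load_reference_ledger",
    "load_reference_area_stats",
    "equivalent_square_side",
]


class LesionType(enum.Enum):
    """The 8 lesion types, keyed by their conventional short codes.

    ``AKIEC`` (actinic keratosis / Bowen's disease) explicitly includes
    squamous cell carcinoma.
    """

    MEL = "Melanoma"
    NV = "Melanocytic Nevus"
    BCC = "Basal Cell Carcinoma"
    AKIEC = "Actinic Keratosis/Bowen's Disease (incl. Squamous Cell Carcinoma)"
    BKL = "Benign Keratosis"
    DF = "Dermatofibroma"
    VASC = "Vascular Lesion"
    OB = "Other Benign"

    @property
    def code(self) -> str:
        return self.name

    @property
    def display_name(self) -> str:
        return self.value

    @classmethod
    def from_code(cls, code: str) -> "LesionType":
        try:
            return cls[code]
        except KeyError:
            raise ValueError(
                f"unknown lesion type code {code!r}; valid codes: "
                f"{[t.name for t in cls]}"
            ) from None


@dataclass(frozen=True)
class LesionTaxonomy:
    """The closed 8-type taxonomy with its malignant subset."""

    types: tuple[LesionType, ...] = tuple(LesionType)
    malignant_set: frozenset[LesionType] = frozenset(
        {LesionType.MEL, LesionType.BCC, LesionType.AKIEC}
    )

    def __post_init__(self) -> None:
        if len(set(self.types)) != len(self.types):
            raise ValueError("duplicate lesion types in taxonomy")
        if not self.malignant_set <= set(self.types):
            raise ValueError("malignant_set must be a subset of types")

    @property
    def benign_set(self) -> frozenset[LesionType]:
        return frozenset(self.types) - self.malignant_set

    def is_malignant(self, lesion_type: LesionType) -> bool:
        return lesion_type in self.malignant_set

    def hash_key(self) -> str:
        """Stable identifier used to check model/taxonomy compatibility."""
        parts = [t.name for t in self.types] + ["|"] + sorted(
            t.name for t in self.malignant_set
        )
        return "-".join(parts)


DEFAULT_TAXONOMY = LesionTaxonomy()


@dataclass(frozen=True)
class RoiBox:
    """One lesion region: center-based continuous pixel box."""

    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"box width/height must be positive, got "
                f"({self.width}, {self.height})"
            )

    @property
    def area(self) -> float:
        return self.width * self.height

    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) under the half-open convention."""
        return (
            self.x_center - self.width / 2.0,
            self.y_center - self.height / 2.0,
            self.x_center + self.width / 2.0,
            self.y_center + self.height / 2.0,
        )

    @classmethod
    def from_corners(
        cls, x_min: float, y_min: float, x_max: float, y_max: float
    ) -> "RoiBox":
        return cls(
            x_center=(x_min + x_max) / 2.0,
            y_center=(y_min + y_max) / 2.0,
            width=x_max - x_min,
            height=y_max - y_min,
        )

    def clipped(
        self, image_width: float, image_height: float, warn: bool = True
    ) -> "RoiBox":
        """Clip to image bounds; raises if the clipped box has zero area."""
        x0, y0, x1, y1 = self.corners()
        cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
        cx1, cy1 = min(x1, float(image_width)), min(y1, float(image_height))
        if cx1 <= cx0 or cy1 <= cy0:
            raise ValueError(
                f"box {self} has zero area after clipping to "
                f"{image_width}x{image_height} image"
            )
        if (cx0, cy0, cx1, cy1) != (x0, y0, x1, y1) and warn:
            logger.warning("box %s clipped to image bounds", self)
        return RoiBox.from_corners(cx0, cy0, cx1, cy1)

    def scaled(self, factor_x: float, factor_y: float | None = None) -> "RoiBox":
        fy = factor_x if factor_y is None else factor_y
        return RoiBox(
            self.x_center * factor_x,
            self.y_center * fy,
            self.width * factor_x,
            self.height * fy,
        )


@dataclass
class AnnotatedImage:
    """An RGB image with its non-empty set of typed lesion boxes.

    The image-level malignancy label is always derived from the ROI types
    (see :func:`image_label`), never stored independently.
    """

    image_id: str
    pixels: np.ndarray  # H x W x 3, uint8
    rois: list[tuple[RoiBox, LesionType]]
    capture_mode: str = "wide_field"  # or "dermoscopy"
    patient_id: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an H x W x 3 array")
        if not self.rois:
            raise ValueError(
                f"image {self.image_id!r} has no ROIs; the data model "
                "requires a non-empty annotation set"
            )
        if self.capture_mode not in ("wide_field", "dermoscopy"):
            raise ValueError(f"unknown capture_mode {self.capture_mode!r}")
        h, w = self.pixels.shape[:2]
        self.rois = [(box.clipped(w, h), t) for box, t in self.rois]

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    def boxes(self) -> list[RoiBox]:
        return [box for box, _ in self.rois]

    def label(self, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY) -> int:
        return image_label(self, taxonomy)


def image_label(
    image: AnnotatedImage, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY
) -> int:
    """Image-level malignancy label: 1 iff any ROI type is malignant."""
    if not image.rois:
        raise ValueError("image has no ROIs")
    return int(any(taxonomy.is_malignant(t) for _, t in image.rois))


@dataclass(frozen=True)
class DatasetLedger:
    """Per-lesion-type counts for a named dataset.

    Types may be absent (e.g. 'other benign' is absent from the public
    ISIC2018 training set); absent means a count of zero.
    """

    name: str
    counts: Mapping[LesionType, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if not isinstance(t, LesionType):
                raise TypeError(f"ledger key {t!r} is not a LesionType")
            if c < 0:
                raise ValueError(f"negative count {c} for {t.name}")

    def count(self, lesion_type: LesionType) -> int:
        return int(self.counts.get(lesion_type, 0))

    @classmethod
    def from_images(
        cls, name: str, images: Iterable[AnnotatedImage]
    ) -> "DatasetLedger":
        counts: dict[LesionType, int] = {}
        for image in images:
            for _, t in image.rois:
                counts[t] = counts.get(t, 0) + 1
        return cls(name=name, counts=counts)


@dataclass(frozen=True)
class LedgerTotals:
    total: int
    malignant_total: int
    benign_total: int
    malignant_percent: int | None  # None when total == 0


def ledger_totals(
    ledger: DatasetLedger, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY
) -> LedgerTotals:
    """Totals under the malignancy mapping; percent is rounded to integer.

    ``malignant_percent`` is ``None`` for an empty ledger (undefined).
    """
    total = sum(ledger.count(t) for t in taxonomy.types)
    malignant = sum(ledger.count(t) for t in taxonomy.malignant_set)
    benign = total - malignant
    percent = None if total == 0 else round(100.0 * malignant / total)
    return LedgerTotals(total, malignant, benign, percent)


def merge_ledgers(a: DatasetLedger, b: DatasetLedger) -> DatasetLedger:
    """Element-wise sum of two ledgers; missing types count as zero."""
    keys = set(a.counts) | set(b.counts)
    return DatasetLedger(
        name=f"{a.name}+{b.name}",
        counts={t: a.count(t) + b.count(t) for t in keys},
    )


def _packaged_csv(filename: str) -> pd.DataFrame:
    with resources.files("lesionkit.data").joinpath(filename).open() as fh:
        return pd.read_csv(fh)


def load_reference_ledger(dataset: str) -> DatasetLedger:
    """Load the packaged per-type lesion counts for a reference dataset.

    Available dataset names: ``discovery`` (institutional smartphone +
    dermoscopy collection), ``isic2018`` (public dermoscopy training set),
    ``test`` (independent test set).
    """
    table = _packaged_csv("lesion_counts.csv")
    sub = table[table["dataset"] == dataset]
    if sub.empty:
        raise ValueError(
            f"unknown dataset {dataset!r}; available: "
            f"{sorted(table['dataset'].unique())}"
        )
    counts = {
        LesionType.from_code(row["lesion_type"]): int(row["count"])
        for _, row in sub.iterrows()
    }
    return DatasetLedger(name=dataset, counts=counts)


def load_reference_area_stats(dataset: str) -> dict[str, int]:
    """Mean lesion/image pixel areas for a reference dataset."""
    table = _packaged_csv("area_stats.csv")
    sub = table[table["dataset"] == dataset]
    if sub.empty:
        raise ValueError(f"no area statistics for dataset {dataset!r}")
    return {
        row["quantity"]: int(row["mean_area_px2"]) for _, row in sub.iterrows()
    }


def equivalent_square_side(area: float) -> int:
    """Integer side of the square with (at most) the given area.

    A mean area of 307,699 px^2 corresponds to a roughly 554 x 554 square.
    """
    if area < 0:
        raise ValueError("area must be non-negative")
    return math.isqrt(int(area))
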