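"""Reading and writing annotated image sets as COCO-style JSON + PNG files.

The on-disk layout is the standard detection-dataset one: a JSON file with
``images``, ``annotations`` and ``categories`` sections, where category names
are the 8 lesion-type codes and boxes are stored in COCO corner format
``[x_min, y_min, width, height]``.  In memory boxes are center-based
(:class:`~lesionkit.taxonomy.RoiBox`); conversion happens at the boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .taxonomy import (
    DEFAULT_TAXONOMY,
    AnnotatedImage,
    LesionTaxonomy,
    LesionType,
    RoiBox,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_annotations",
    "write_annotations",
    "boxes_to_coco_detections",
    "patient_split",
]

_BOX_PRECISION = 3  # decimals kept when serializing box coordinates


def _category_table(taxonomy: LesionTaxonomy) -> list[dict]:
    return [
        {"id": i + 1, "name": t.name, "supercategory": "lesion"}
        for i, t in enumerate(taxonomy.types)
    ]


def write_annotations(
    images: Sequence[AnnotatedImage],
    path: str | Path,
    images_dir: str | Path | None = None,
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
) -> Path:
    """Write images as PNGs plus a COCO-style annotation JSON.

    ``images_dir`` defaults to a directory named ``images`` next to the JSON
    file.  Returns the JSON path.
    """
    path = Path(path)
    images_dir = Path(images_dir) if images_dir else path.parent / "images"
    images_dir.mkdir(parents=True, exist_ok=True)
    cat_id = {t.name: i + 1 for i, t in enumerate(taxonomy.types)}

    image_entries, ann_entries = [], []
    ann_id = 1
    for idx, image in enumerate(images):
        file_name = f"{image.image_id}.png"
        Image.fromarray(np.asarray(image.pixels, dtype=np.uint8)).save(
            images_dir / file_name
        )
        image_entries.append(
            {
                "id": idx + 1,
                "image_id": image.image_id,
                "file_name": file_name,
                "width": image.width,
                "height": image.height,
                "patient_id": image.patient_id,
                "capture_mode": image.capture_mode,
            }
        )
        for box, lesion_type in image.rois:
            x0, y0, x1, y1 = box.corners()
            ann_entries.append(
                {
                    "id": ann_id,
                    "image_id": idx + 1,
                    "category_id": cat_id[lesion_type.name],
                    "bbox": [
                        round(x0, _BOX_PRECISION),
                        round(y0, _BOX_PRECISION),
                        round(box.width, _BOX_PRECISION),
                        round(box.height, _BOX_PRECISION),
                    ],
                    "area": round(box.area, _BOX_PRECISION),
                    "iscrowd": 0,
                }
            )
            ann_id += 1

    payload = {
        "images": image_entries,
        "annotations": ann_entries,
        "categories": _category_table(taxonomy),
    }
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return path


def read_annotations(
    path: str | Path,
    images_dir: str | Path | None = None,
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
) -> list[AnnotatedImage]:
    """Read a COCO-style annotation JSON back into annotated images.

    Category names must be exactly the 8 lesion-type codes; an unknown name
    is an error.  Every listed image must have at least one annotation.
    Boxes extending past the image bounds are clipped (with a warning) by the
    :class:`AnnotatedImage` constructor.
    """
    path = Path(path)
    images_dir = Path(images_dir) if images_dir else path.parent / "images"
    with open(path) as fh:
        payload = json.load(fh)

    known = {t.name for t in taxonomy.types}
    cat_to_type: dict[int, LesionType] = {}
    for cat in payload.get("categories", []):
        if cat["name"] not in known:
            raise ValueError(
                f"annotation file {path} declares unknown lesion category "
                f"{cat['name']!r}; the taxonomy is closed to {sorted(known)}"
            )
        cat_to_type[cat["id"]] = LesionType.from_code(cat["name"])

    rois_by_image: dict[int, list[tuple[RoiBox, LesionType]]] = {}
    for ann in payload.get("annotations", []):
        x0, y0, w, h = ann["bbox"]
        box = RoiBox(x0 + w / 2.0, y0 + h / 2.0, w, h)
        if ann["category_id"] not in cat_to_type:
            raise ValueError(
                f"annotation {ann.get('id')} refers to undeclared category "
                f"id {ann['category_id']}"
            )
        rois_by_image.setdefault(ann["image_id"], []).append(
            (box, cat_to_type[ann["category_id"]])
        )

    images = []
    for entry in payload["images"]:
        rois = rois_by_image.get(entry["id"], [])
        if not rois:
            raise ValueError(
                f"image {entry.get('image_id', entry['id'])!r} has no "
                "annotations; the data model requires a non-empty ROI set"
            )
        pixels = np.asarray(Image.open(images_dir / entry["file_name"]))
        images.append(
            AnnotatedImage(
                image_id=str(entry.get("image_id", entry["id"])),
                pixels=pixels,
                rois=rois,
                capture_mode=entry.get("capture_mode", "wide_field"),
                patient_id=str(entry.get("patient_id", "")),
            )
        )
    return images


def boxes_to_coco_detections(
    image_ids: Sequence[str],
    boxes_per_image: Sequence[Sequence[RoiBox]],
    scores_per_image: Sequence[Sequence[float]],
    category_ids: Sequence[Sequence[int]] | None = None,
) -> list[dict]:
    """Export predicted boxes in COCO detection-results format."""
    out = []
    for n, image_id in enumerate(image_ids):
        boxes, scores = boxes_per_image[n], scores_per_image[n]
        cats = category_ids[n] if category_ids is not None else [1] * len(boxes)
        for box, score, cat in zip(boxes, scores, cats):
            x0, y0, _, _ = box.corners()
            out.append(
                {
                    "image_id": image_id,
                    "category_id": int(cat),
                    "bbox": [x0, y0, box.width, box.height],
                    "score": float(score),
                }
            )
    return out


def patient_split(
    images: Sequence[AnnotatedImage],
    test_fraction: float = 0.15,
    seed: int = 0,
) -> tuple[list[AnnotatedImage], list[AnnotatedImage]]:
    """Split at the patient level: all images of a patient land in one side.

    The split is seeded and reproducible.  Patients are shuffled and assigned
    to the held-out side until it holds at least ``test_fraction`` of the
    images.
    """
    if not 0.0 <= test_fraction < 1.0:
        raise ValueError("test_fraction must be in [0, 1)")
    by_patient: dict[str, list[AnnotatedImage]] = {}
    for image in images:
        by_patient.setdefault(image.patient_id or image.image_id, []).append(
            image
        )
    patients = sorted(by_patient)
    rng = np.random.default_rng(seed)
    rng.shuffle(patients)

    target = test_fraction * len(images)
    test_patients: set[str] = set()
    held = 0
    for patient in patients:
        if held >= target:
            break
        test_patients.add(patient)
        held += len(by_patient[patient])

    train = [im for im in images if (im.patient_id or im.image_id) not in test_patients]
    test = [im for im in images if (im.patient_id or im.image_id) in test_patients]
    return train, test
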