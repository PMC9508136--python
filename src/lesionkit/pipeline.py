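"""Orchestration: seeded end-to-end benchmark tying simulation, training,
prediction and evaluation together.

``run_benchmark`` reproduces, on the synthetic benchmark, the structure of
the full-scale study's result tables: a granularity comparison (three
detector granularities x five detection metrics), a strategy comparison
(four image-level strategies x AUC/AP), an aggregator grid (three detectors
x three aggregators), and a clinical-covariate ablation.  Every cell is
traceable to a seeded sub-run; partial failures are recorded per cell and
the run continues.

All randomness flows from ``global_seed`` through named per-stage
substreams (CRC32 of the stage name mixed into the seed), so stages stay
decoupled: changing, say, the number of test images does not silently
reshuffle detector training.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .aggregation import ImageMalignancyScorer, StrategySpec
from .classifier import MalignancyCropClassifier, crop_dataset
from .clinical import ClinicalLogisticModel, CombinedMalignancyModel
from .detector import LesionDetector
from .metrics import (
    ScoredPredictionSet,
    average_precision,
    map_at,
    recall_and_iou_summary,
    roc_auc,
)
from .simulate import CovariateConfig, SimConfig, generate_covariates, generate_dataset
from .taxonomy import DEFAULT_TAXONOMY, AnnotatedImage, LesionTaxonomy

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "stage_seed",
    "run_benchmark",
    "detection_pred_set",
    "train_benchmark_models",
]

GRANULARITIES = ("one_class", "malignancy", "sub_type")
GRID_AGGREGATORS = ("average", "noisy_or", "maximum")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    return (int(global_seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """Configuration of a benchmark run at desk scale."""

    global_seed: int = 0
    n_train_images: int = 60
    n_test_images: int = 40
    input_side: int = 32
    work_side: int = 128
    detector_epochs: int = 12
    classifier_epochs: int = 40
    combined_epochs: int = 30
    appearance_separation: float = 0.8
    sim_overrides: dict = field(default_factory=dict)

    def sim_config(self, stage: str) -> SimConfig:
        return SimConfig(
            appearance_separation=self.appearance_separation,
            seed=stage_seed(self.global_seed, stage),
            **self.sim_overrides,
        )

    def to_dict(self) -> dict:
        return asdict(self)


def detection_pred_set(
    detector: LesionDetector, images: Sequence[AnnotatedImage]
) -> ScoredPredictionSet:
    """Run a detector over a set and package results for the metric suite."""
    predictions, ground_truth = {}, {}
    for image in images:
        result = detector.detect(image)
        predictions[image.image_id] = list(zip(result.boxes, result.scores))
        ground_truth[image.image_id] = image.boxes()
    return ScoredPredictionSet(predictions, ground_truth)


def _detection_metrics(
    detector: LesionDetector, images: Sequence[AnnotatedImage]
) -> dict:
    pred_set = detection_pred_set(detector, images)
    report = map_at(pred_set, thresholds=(0.5, 0.75))
    summary = recall_and_iou_summary(pred_set)
    report["recall_iou_gt0"] = summary.recall_iou_gt0
    report["median_iou"] = summary.median_iou
    report["q1_iou"] = summary.q1_iou
    report["q3_iou"] = summary.q3_iou
    return report


def _auc_ap(scores, labels) -> dict:
    return {
        "auc": roc_auc(scores, labels),
        "ap": average_precision(scores, labels),
    }


def train_benchmark_models(config: RunConfig, taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY):
    """Simulate the benchmark data and train every model variant.

    Returns a dict with train/test image sets, the crop-level and direct
    whole-image classifiers, and one detector per granularity.
    """
    train = generate_dataset(config.sim_config("train"), config.n_train_images)
    test = generate_dataset(config.sim_config("test"), config.n_test_images)

    crops, crop_labels = crop_dataset(
        train, taxonomy, input_side=config.input_side
    )
    crop_model = MalignancyCropClassifier(
        input_side=config.input_side,
        epochs=config.classifier_epochs,
        seed=stage_seed(config.global_seed, "crop_model"),
    ).fit(crops, crop_labels)

    whole = np.stack(
        [
            crop_model._as_crop_batch(im.pixels[None])[0]  # resize whole image
            for im in train
        ]
    )
    direct_model = MalignancyCropClassifier(
        input_side=config.input_side,
        epochs=config.classifier_epochs,
        seed=stage_seed(config.global_seed, "direct_model"),
    ).fit(whole, np.array([im.label(taxonomy) for im in train]))

    detectors = {}
    for granularity in GRANULARITIES:
        detectors[granularity] = LesionDetector(
            granularity=granularity,
            epochs=config.detector_epochs,
            input_side=config.input_side,
            work_side=config.work_side,
            seed=stage_seed(config.global_seed, f"detector_{granularity}"),
        ).fit(train, taxonomy)

    return {
        "train": train,
        "test": test,
        "crop_model": crop_model,
        "direct_model": direct_model,
        "detectors": detectors,
    }


def _safe(cell_fn):
    try:
        return cell_fn()
    except Exception as exc:  # recorded per cell; the run continues
        logger.warning("benchmark cell failed: %s", exc)
        return {"error": f"{type(exc).__name__}: {exc}"}


def run_benchmark(
    config: RunConfig | None = None,
    taxonomy: LesionTaxonomy = DEFAULT_TAXONOMY,
    models: dict | None = None,
) -> dict:
    """Run the full synthetic benchmark and return a structured report.

    ``models`` may carry the output of :func:`train_benchmark_models` to
    reuse already-trained models.
    """
    config = config or RunConfig()
    if models is None:
        models = train_benchmark_models(config, taxonomy)
    test = models["test"]
    detectors = models["detectors"]
    crop_model = models["crop_model"]
    direct_model = models["direct_model"]
    y_image = np.array([im.label(taxonomy) for im in test])

    report: dict = {
        "config": config.to_dict(),
        "seeds": {
            stage: stage_seed(config.global_seed, stage)
            for stage in ("train", "test", "crop_model", "direct_model")
        },
        "versions": _versions(),
    }

    # --- granularity x detection metrics (Table-3 shape: 3 x 5) ---------
    report["granularity_table"] = {
        g: _safe(lambda g=g: _detection_metrics(detectors[g], test))
        for g in GRANULARITIES
    }

    # --- strategies x AUC/AP (Table-4 shape: 4 x 2) ----------------------
    def strategy_scorer(strategy: str, detector_name: str | None) -> ImageMalignancyScorer:
        return ImageMalignancyScorer(
            spec=StrategySpec(strategy=strategy, aggregator="maximum"),
            detector=detectors[detector_name] if detector_name else None,
            crop_model=crop_model,
            direct_model=direct_model,
            taxonomy=taxonomy,
        )

    strategies = {
        "image_level": ("direct", None),
        "two_stage_one_class": ("two_stage", "one_class"),
        "one_step_malignancy": ("one_step", "malignancy"),
        "one_step_sub_type": ("one_step", "sub_type"),
    }
    report["strategy_table"] = {
        name: _safe(
            lambda args=args: _auc_ap(
                strategy_scorer(*args).predict_proba(test), y_image
            )
        )
        for name, args in strategies.items()
    }

    # --- aggregator grid (Table-5 shape: 3 detectors x 3 aggregators) ----
    grid: dict = {}
    for g in GRANULARITIES:
        row: dict = {}
        # reuse detections+crop scores across the three aggregators
        for agg in GRID_AGGREGATORS:
            scorer = ImageMalignancyScorer(
                spec=StrategySpec(strategy="two_stage", aggregator=agg),
                detector=detectors[g],
                crop_model=crop_model,
                taxonomy=taxonomy,
            )
            row[agg] = _safe(
                lambda s=scorer: _auc_ap(s.predict_proba(test), y_image)
            )
        grid[g] = row
    report["aggregator_grid"] = grid

    # --- clinical-covariate ablation (no-signal covariates) --------------
    report["clinical_ablation"] = _safe(
        lambda: _clinical_ablation(config, models, taxonomy)
    )
    return report


def _clinical_ablation(config: RunConfig, models: dict, taxonomy) -> dict:
    """Clinical-only vs image-only vs combined, with no-signal covariates."""
    null_cov = CovariateConfig(
        numeric_covariates=(
            ("age", 62.0, 14.0, 0.0),
            ("prior_visits", 3.0, 2.0, 0.0),
        ),
        categorical_covariates=(("sex", ("F", "M"), (0.0, 0.0)),),
        seed=stage_seed(config.global_seed, "covariates"),
    )
    train, test = models["train"], models["test"]
    crop_model = models["crop_model"]
    table_train, y_train = generate_covariates(train, null_cov, taxonomy)
    table_test, y_test = generate_covariates(
        test,
        CovariateConfig(
            numeric_covariates=null_cov.numeric_covariates,
            categorical_covariates=null_cov.categorical_covariates,
            seed=stage_seed(config.global_seed, "covariates_test"),
        ),
        taxonomy,
    )

    clinical = ClinicalLogisticModel().fit(
        table_train.drop(columns=["image_id", "patient_id"]), y_train
    )
    clinical_auc = roc_auc(
        clinical.predict_proba(
            table_test.drop(columns=["image_id", "patient_id"])
        )[:, 1],
        y_test,
    )

    # image-only vs combined, at crop level with per-image covariates
    def crop_table(images, table):
        rows, crops, labels = [], [], []
        lookup = table.set_index("image_id")
        for image in images:
            for box, lesion_type in image.rois:
                from .classifier import extract_crop

                crops.append(
                    extract_crop(image.pixels, box, config.input_side, 0.1)
                )
                rows.append(lookup.loc[image.image_id])
                labels.append(int(taxonomy.is_malignant(lesion_type)))
        import pandas as pd

        return (
            np.stack(crops),
            pd.DataFrame(rows).reset_index(drop=True),
            np.array(labels),
        )

    crops_tr, tab_tr, y_tr = crop_table(train, table_train)
    crops_te, tab_te, y_te = crop_table(test, table_test)
    combined = CombinedMalignancyModel(
        crop_model=crop_model,
        epochs=config.combined_epochs,
        seed=stage_seed(config.global_seed, "combined"),
    ).fit(crops_tr, tab_tr.drop(columns=["patient_id"], errors="ignore"), y_tr)

    image_only_auc = roc_auc(crop_model.predict_proba(crops_te)[:, 1], y_te)
    combined_auc = roc_auc(
        combined.predict_proba(
            crops_te, tab_te.drop(columns=["patient_id"], errors="ignore")
        )[:, 1],
        y_te,
    )
    return {
        "clinical_only_auc": clinical_auc,
        "image_only_auc": image_only_auc,
        "combined_auc": combined_auc,
        "combined_minus_image_only": combined_auc - image_only_auc,
        "frozen_backbone_intact": combined.frozen_hash_before_
        == combined.frozen_hash_after_,
    }


def _versions() -> dict:
    import skimage
    import sklearn

    import lesionkit

    return {
        "lesionkit": lesionkit.__version__,
        "numpy": np.__version__,
        "scikit-learn": sklearn.__version__,
        "scikit-image": skimage.__version__,
    }
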