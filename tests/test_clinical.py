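"""Clinical covariate model and image+covariate fusion."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lesionkit.clinical import (
    ClinicalLogisticModel,
    CombinedMalignancyModel,
    CovariatePreprocessor,
)
from lesionkit.metrics import roc_auc
from lesionkit.simulate import CovariateConfig, SimConfig, generate_covariates, generate_dataset


def _driven_table(effects, n=2000, seed=11, intercept=0.0):
    images = generate_dataset(SimConfig(seed=1, image_size_range=(48, 64)), 50)
    images = images * (n // 50)
    cfg = CovariateConfig(
        numeric_covariates=effects,
        categorical_covariates=(),
        intercept=intercept,
        seed=seed,
    )
    table, labels = generate_covariates(images, cfg, mode="covariate_driven")
    return table.drop(columns=["image_id", "patient_id"]), labels


class TestClinicalLogisticModel:
    def test_recovers_known_coefficients_within_20_percent(self):
        effects = (("a", 0.0, 1.0, 1.2), ("b", 10.0, 2.0, -0.8))
        table, labels = _driven_table(effects)
        model = ClinicalLogisticModel().fit(table, labels)
        coefs = model.coefficients()
        # inputs are standardized, so coefficients are on the logit-per-SD scale
        assert coefs["a"] == pytest.approx(1.2, rel=0.2)
        assert coefs["b"] == pytest.approx(-0.8, rel=0.2)

    def test_no_signal_gives_chance_auc_on_held_out_rows(self):
        effects = (("a", 0.0, 1.0, 0.0), ("b", 5.0, 1.0, 0.0))
        table, labels = _driven_table(effects, n=3000, seed=21)
        train_t, test_t = table.iloc[:2000], table.iloc[2000:]
        train_y, test_y = labels[:2000], labels[2000:]
        model = ClinicalLogisticModel().fit(train_t, train_y)
        auc = roc_auc(model.predict_proba(test_t)[:, 1], test_y)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_one_hot_indicators_sum_to_one_per_row(self):
        table = pd.DataFrame({"color": ["r", "g", "b", "g", "r", "b"]})
        pre = CovariatePreprocessor(numeric_names=[], categorical_names=["color"])
        X = pre.fit_transform(table)
        # 3 observed levels + explicit missing level
        assert X.shape == (6, 4)
        assert np.allclose(X.sum(axis=1), 1.0)

    def test_constant_covariate_dropped_with_warning(self, caplog):
        import logging

        table = pd.DataFrame({"c": [1.0] * 20, "x": np.arange(20.0)})
        y = (np.arange(20) % 2).astype(int)
        with caplog.at_level(logging.WARNING, logger="lesionkit.clinical"):
            model = ClinicalLogisticModel().fit(table, y)
        assert "c" not in model.coefficients().index
        assert any("constant covariate" in r.message for r in caplog.records)

    def test_unseen_level_maps_to_zero_block(self, caplog):
        import logging

        table = pd.DataFrame({"site": ["arm", "leg", "arm", "leg"]})
        y = np.array([0, 1, 0, 1])
        model = ClinicalLogisticModel().fit(table, y)
        new = pd.DataFrame({"site": ["torso"]})
        with caplog.at_level(logging.WARNING, logger="lesionkit.clinical"):
            X = model.preprocessor_.transform(new)
        assert np.allclose(X, 0.0)
        assert any("unseen level" in r.message for r in caplog.records)

    def test_prediction_uses_training_statistics_only(self):
        effects = (("a", 0.0, 1.0, 1.0),)
        table, labels = _driven_table(effects, n=1000)
        model = ClinicalLogisticModel().fit(table, labels)
        first = model.predict_proba(table)
        second = model.predict_proba(table)
        assert np.array_equal(first, second)

    def test_single_class_rejected(self):
        table = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            ClinicalLogisticModel().fit(table, [1, 1])

    def test_missing_numeric_imputed_with_training_mean(self):
        table = pd.DataFrame({"x": [1.0, 3.0, np.nan, 2.0]})
        pre = CovariatePreprocessor(numeric_names=["x"], categorical_names=[])
        X = pre.fit_transform(table)
        assert X[2, 0] == pytest.approx(0.0)  # mean-imputed -> standardized 0


@pytest.fixture(scope="module")
def fusion_data(bench_models):
    """Crops and per-image covariates for the train/test benchmark sets."""
    train, test = bench_models["train"], bench_models["test"]

    def build(images, cov_seed, effect):
        cfg = CovariateConfig(
            numeric_covariates=(("risk", 0.0, 1.0, effect),),
            categorical_covariates=(),
            seed=cov_seed,
        )
        table, _ = generate_covariates(images, cfg)
        lookup = table.set_index("image_id")
        crops, labels, rows = [], [], []
        from lesionkit.classifier import extract_crop
        from lesionkit.taxonomy import DEFAULT_TAXONOMY

        for im in images:
            for box, t in im.rois:
                crops.append(extract_crop(im.pixels, box, 32, 0.1))
                labels.append(int(DEFAULT_TAXONOMY.is_malignant(t)))
                rows.append({"risk": lookup.loc[im.image_id, "risk"]})
        return np.stack(crops), pd.DataFrame(rows), np.array(labels)

    return {
        "null": (build(train, 100, 0.0), build(test, 101, 0.0)),
    }


class TestCombinedModel:
    def test_convolutional_layers_frozen_during_fusion_training(
        self, bench_models, fusion_data
    ):
        (crops, table, y), _ = fusion_data["null"]
        model = CombinedMalignancyModel(
            crop_model=bench_models["crop_model"], seed=0
        ).fit(crops, table, y)
        assert model.frozen_hash_before_ == model.frozen_hash_after_

    def test_no_signal_covariates_leave_auc_within_005_of_image_only(
        self, bench_models, fusion_data
    ):
        (crops_tr, tab_tr, y_tr), (crops_te, tab_te, y_te) = fusion_data["null"]
        crop_model = bench_models["crop_model"]
        combined = CombinedMalignancyModel(crop_model=crop_model, seed=0).fit(
            crops_tr, tab_tr, y_tr
        )
        image_auc = roc_auc(crop_model.predict_proba(crops_te)[:, 1], y_te)
        combined_auc = roc_auc(
            combined.predict_proba(crops_te, tab_te)[:, 1], y_te
        )
        assert combined_auc == pytest.approx(image_auc, abs=0.05)

    def test_covariate_only_signal_lifts_auc_by_at_least_01(self):
        """Positive control: when images carry no appearance signal
        (separation 0) and labels are drawn from a strong covariate, the
        fusion model must clearly beat the image-only model."""
        from lesionkit.classifier import MalignancyCropClassifier, extract_crop

        def build(seed, cov_seed, n):
            images = generate_dataset(
                SimConfig(seed=seed, appearance_separation=0.0), n
            )
            cfg = CovariateConfig(
                numeric_covariates=(("risk", 0.0, 1.0, 3.0),),
                categorical_covariates=(),
                intercept=0.0,
                seed=cov_seed,
            )
            table, labels = generate_covariates(
                images, cfg, mode="covariate_driven"
            )
            lookup = table.set_index("image_id")
            crops, ys, rows = [], [], []
            for im, y in zip(images, labels):
                for box, _ in im.rois:
                    crops.append(extract_crop(im.pixels, box, 32, 0.1))
                    ys.append(y)
                    rows.append({"risk": lookup.loc[im.image_id, "risk"]})
            return np.stack(crops), pd.DataFrame(rows), np.array(ys)

        crops_tr, tab_tr, y_tr = build(61, 201, 80)
        crops_te, tab_te, y_te = build(62, 202, 50)
        crop_model = MalignancyCropClassifier(
            input_side=32, epochs=30, seed=3
        ).fit(crops_tr, y_tr)
        combined = CombinedMalignancyModel(crop_model=crop_model, seed=0).fit(
            crops_tr, tab_tr, y_tr
        )
        image_auc = roc_auc(crop_model.predict_proba(crops_te)[:, 1], y_te)
        combined_auc = roc_auc(
            combined.predict_proba(crops_te, tab_te)[:, 1], y_te
        )
        assert combined_auc >= image_auc + 0.1

    def test_zeroed_covariates_degrade_gracefully(self, bench_models, fusion_data):
        (crops_tr, tab_tr, y_tr), (crops_te, tab_te, y_te) = fusion_data["null"]
        crop_model = bench_models["crop_model"]
        combined = CombinedMalignancyModel(crop_model=crop_model, seed=0).fit(
            crops_tr, tab_tr, y_tr
        )
        zeroed = combined.predict_proba(crops_te, zero_covariates=True)[:, 1]
        image_only = crop_model.predict_proba(crops_te)[:, 1]
        rho = spearmanr(zeroed, image_only).statistic
        assert rho >= 0.8

    def test_unmatched_covariate_rows_rejected_listing_ids(self, bench_models):
        crops = np.zeros((2, 32, 32, 3), np.uint8)
        table = pd.DataFrame({"image_id": ["a"], "risk": [0.1]})
        with pytest.raises(ValueError, match="b"):
            CombinedMalignancyModel(crop_model=bench_models["crop_model"]).fit(
                crops, table, [0, 1], image_ids=["a", "b"]
            )

    def test_unfitted_backbone_rejected(self):
        from lesionkit.classifier import MalignancyCropClassifier

        with pytest.raises(ValueError, match="fitted"):
            CombinedMalignancyModel(crop_model=MalignancyCropClassifier()).fit(
                np.zeros((2, 32, 32, 3), np.uint8),
                pd.DataFrame({"x": [0.0, 1.0]}),
                [0, 1],
            )
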