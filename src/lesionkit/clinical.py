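"""Clinical-covariate models: covariates-only logistic regression and
image+covariate fusion.

The covariates-only model is a logistic regression over standardized numeric
covariates and one-hot-encoded categorical covariates.  Standardization
statistics (mean, SD) are fitted on training rows only and reused verbatim
at prediction time, so there is no train/test leakage.  Degenerate numeric
covariates (zero SD) are dropped with a warning; missing numeric values are
imputed with the training mean and missing categorical values map to an
explicit ``"missing"`` level; a level never seen in training maps to an
all-zero indicator block with a logged warning.

The combined model keeps the trained crop-level malignancy classifier as a
frozen feature extractor (no convolutional parameter changes — verifiable
by parameter hash), concatenates its global-average-pooled features with the
standardized covariates, and trains only a fully connected sigmoid head
(SGD, 30 epochs, batch 64, initial learning rate 0.001, momentum 0.9,
weight decay 1e-4, cosine schedule).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted

from .classifier import MalignancyCropClassifier
from .nn import cosine_lr, parameter_hash

logger = logging.getLogger(__name__)

__all__ = [
    "CovariatePreprocessor",
    "ClinicalLogisticModel",
    "CombinedMalignancyModel",
]

_MISSING = "missing"
_ID_COLUMNS = ("image_id", "patient_id")


class CovariatePreprocessor:
    """Standardize numerics, one-hot categoricals; training statistics only."""

    def __init__(
        self,
        numeric_names: list[str] | None = None,
        categorical_names: list[str] | None = None,
    ):
        self.numeric_names = numeric_names
        self.categorical_names = categorical_names

    def fit(self, table: pd.DataFrame) -> "CovariatePreprocessor":
        num = self.numeric_names
        cat = self.categorical_names
        if num is None:
            num = [
                c
                for c in table.columns
                if c not in _ID_COLUMNS
                and pd.api.types.is_numeric_dtype(table[c])
            ]
        if cat is None:
            cat = [
                c for c in table.columns if c not in _ID_COLUMNS and c not in num
            ]
        self.means_, self.sds_ = {}, {}
        self.numeric_used_ = []
        for c in num:
            col = pd.to_numeric(table[c], errors="coerce")
            mean = float(col.mean())
            sd = float(col.std(ddof=0))
            if not sd > 0:
                logger.warning("dropping constant covariate %r (sd=0)", c)
                continue
            self.means_[c], self.sds_[c] = mean, sd
            self.numeric_used_.append(c)
        self.levels_ = {}
        for c in cat:
            observed = sorted(
                str(v) for v in table[c].dropna().unique()
            )
            self.levels_[c] = observed + [_MISSING]
        self.feature_names_ = list(self.numeric_used_) + [
            f"{c}={lv}" for c in self.levels_ for lv in self.levels_[c]
        ]
        return self

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "feature_names_"):
            raise RuntimeError("CovariatePreprocessor.transform before fit")
        n = len(table)
        blocks = []
        for c in self.numeric_used_:
            col = pd.to_numeric(table[c], errors="coerce").to_numpy(float)
            col = np.where(np.isnan(col), self.means_[c], col)
            blocks.append(((col - self.means_[c]) / self.sds_[c])[:, None])
        for c, levels in self.levels_.items():
            block = np.zeros((n, len(levels)))
            values = table[c].astype(object).where(table[c].notna(), _MISSING)
            for i, v in enumerate(values):
                v = str(v)
                if v in levels:
                    block[i, levels.index(v)] = 1.0
                else:
                    logger.warning(
                        "unseen level %r for covariate %r maps to an "
                        "all-zero indicator block",
                        v,
                        c,
                    )
            blocks.append(block)
        if not blocks:
            return np.zeros((n, 0))
        return np.hstack(blocks)

    def fit_transform(self, table: pd.DataFrame) -> np.ndarray:
        return self.fit(table).transform(table)


class ClinicalLogisticModel(BaseEstimator, ClassifierMixin):
    """Covariates-only logistic regression with standardized inputs."""

    def __init__(
        self,
        numeric_names: list[str] | None = None,
        categorical_names: list[str] | None = None,
        max_iter: int = 500,
        C: float = 1e6,
    ):
        self.numeric_names = numeric_names
        self.categorical_names = categorical_names
        self.max_iter = max_iter
        self.C = C

    def fit(self, table: pd.DataFrame, y) -> "ClinicalLogisticModel":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("both classes must be present")
        self.preprocessor_ = CovariatePreprocessor(
            self.numeric_names, self.categorical_names
        )
        X = self.preprocessor_.fit_transform(table)
        self.model_ = LogisticRegression(C=self.C, max_iter=self.max_iter)
        with warnings.catch_warnings():
            warnings.filterwarnings("always", category=ConvergenceWarning)
            self.model_.fit(X, y)
        if not np.all(np.isfinite(self.model_.coef_)):
            raise RuntimeError("logistic regression produced non-finite coefficients")
        self.classes_ = self.model_.classes_
        return self

    def coefficients(self) -> pd.Series:
        check_is_fitted(self, "model_")
        return pd.Series(
            self.model_.coef_[0], index=self.preprocessor_.feature_names_
        )

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        check_is_fitted(self, "model_")
        return self.model_.predict_proba(self.preprocessor_.transform(table))

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(table)[:, 1] >= 0.5).astype(int)


@dataclass
class _LinearHead:
    """Single fully connected layer + sigmoid, trained with momentum SGD."""

    w: np.ndarray
    b: float

    @classmethod
    def train(
        cls,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        lr_init: float,
        momentum: float,
        weight_decay: float,
        seed: int,
    ) -> tuple["_LinearHead", list[float]]:
        rng = np.random.default_rng(seed)
        n, d = X.shape
        w = rng.normal(0.0, 0.01, d)
        b = 0.0
        vw, vb = np.zeros(d), 0.0
        steps_per_epoch = max(1, math.ceil(n / batch_size))
        t_max = epochs * steps_per_epoch
        t = 0
        history = []
        for _ in range(epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(steps_per_epoch):
                idx = order[s * batch_size : (s + 1) * batch_size]
                if idx.size == 0:
                    continue
                z = X[idx] @ w + b
                p = 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))
                losses.append(
                    float(
                        np.mean(
                            np.maximum(z, 0) - z * y[idx] + np.log1p(np.exp(-np.abs(z)))
                        )
                    )
                )
                g = (p - y[idx]) / idx.size
                gw = X[idx].T @ g + weight_decay * w
                gb = g.sum()
                lr = cosine_lr(t, t_max, lr_init)
                vw = momentum * vw - lr * gw
                vb = momentum * vb - lr * gb
                w = w + vw
                b = b + vb
                t += 1
            history.append(float(np.mean(losses)))
        return cls(w=w, b=float(b)), history

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.w + self.b
        return 1.0 / (1.0 + np.exp(-np.clip(z, -30, 30)))


class CombinedMalignancyModel(BaseEstimator, ClassifierMixin):
    """Image + covariate fusion over a frozen crop-classifier backbone."""

    def __init__(
        self,
        crop_model: MalignancyCropClassifier | None = None,
        numeric_names: list[str] | None = None,
        categorical_names: list[str] | None = None,
        epochs: int = 30,
        batch_size: int = 64,
        lr_init: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 1e-4,
        seed: int = 0,
    ):
        self.crop_model = crop_model
        self.numeric_names = numeric_names
        self.categorical_names = categorical_names
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_init = lr_init
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.seed = seed

    def _check_alignment(self, crops, table, image_ids) -> pd.DataFrame:
        if image_ids is not None:
            if "image_id" not in table.columns:
                raise ValueError("table lacks an image_id column for matching")
            lookup = table.set_index("image_id")
            missing = [i for i in image_ids if i not in lookup.index]
            if missing:
                raise ValueError(
                    f"covariate rows unmatched to images: {missing}"
                )
            return lookup.loc[list(image_ids)].reset_index()
        if len(table) != len(crops):
            raise ValueError(
                f"{len(table)} covariate rows for {len(crops)} crops; pass "
                "image_ids to match by id"
            )
        return table

    def fit(
        self,
        crops: np.ndarray,
        table: pd.DataFrame,
        y,
        image_ids=None,
    ) -> "CombinedMalignancyModel":
        if self.crop_model is None or not hasattr(self.crop_model, "net_"):
            raise ValueError("a fitted MalignancyCropClassifier is required")
        table = self._check_alignment(crops, table, image_ids)
        y = np.asarray(y, dtype=int)

        conv_names = self.crop_model.net_.conv_parameter_names()
        self.frozen_hash_before_ = parameter_hash(self.crop_model.net_, conv_names)

        feats = self.crop_model.crop_features(crops)
        self.preprocessor_ = CovariatePreprocessor(
            self.numeric_names, self.categorical_names
        )
        cov = self.preprocessor_.fit_transform(table)
        self.n_covariate_features_ = cov.shape[1]
        X = np.hstack([cov, feats])
        self.head_, self.loss_history_ = _LinearHead.train(
            X,
            y,
            epochs=self.epochs,
            batch_size=self.batch_size,
            lr_init=self.lr_init,
            momentum=self.momentum,
            weight_decay=self.weight_decay,
            seed=self.seed,
        )
        # all convolutional layers stay frozen during fusion training
        self.frozen_hash_after_ = parameter_hash(self.crop_model.net_, conv_names)
        self.classes_ = np.array([0, 1])
        return self

    def _features(
        self, crops, table, image_ids, zero_covariates: bool
    ) -> np.ndarray:
        feats = self.crop_model.crop_features(crops)
        if zero_covariates or table is None:
            cov = np.zeros((len(feats), self.n_covariate_features_))
        else:
            table = self._check_alignment(crops, table, image_ids)
            cov = self.preprocessor_.transform(table)
        return np.hstack([cov, feats])

    def predict_proba(
        self,
        crops: np.ndarray,
        table: pd.DataFrame | None = None,
        image_ids=None,
        zero_covariates: bool = False,
    ) -> np.ndarray:
        check_is_fitted(self, "head_")
        p = self.head_.predict_proba(
            self._features(crops, table, image_ids, zero_covariates)
        )
        return np.column_stack([1.0 - p, p])

    def predict(self, crops, table=None, image_ids=None) -> np.ndarray:
        return (self.predict_proba(crops, table, image_ids)[:, 1] >= 0.5).astype(int)
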