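"""Monotonically-constrained gradient-boosted models for ctDNA sufficiency.

Thin sklearn-style wrappers around XGBoost. The classifier targets the
binary label ctDNA >= 2% with a logistic objective; the regressor predicts
the fraction itself and is optimized for mean absolute error. Established
tumor-burden markers (PSA, LDH, ALP, cfDNA concentration) are constrained to
a monotone non-decreasing relationship with predicted ctDNA burden;
``colsample_bytree`` and ``colsample_bylevel`` are always tied to
``subsample`` to keep the hyperparameter space manageable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError

__all__ = [
    "HyperGrid",
    "MonotoneBoostedClassifier",
    "MonotoneBoostedRegressor",
    "train_classifier",
    "train_regressor",
]

SUFFICIENCY_THRESHOLD = 0.02


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter search space for the boosted models.

    The default values span 6 * 7 * 5 * 3 = 630 candidates; column-sampling
    rates are not free dimensions — each candidate uses its ``subsample``
    value for ``colsample_bytree`` and ``colsample_bylevel``.
    """

    num_round: tuple[int, ...] = (10, 20, 50, 100, 200, 500)
    max_depth: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    eta: tuple[float, ...] = (0.005, 0.01, 0.02, 0.05, 0.1)
    subsample: tuple[float, ...] = (0.25, 0.5, 0.75)

    def __post_init__(self) -> None:
        if not (self.num_round and self.max_depth and self.eta and self.subsample):
            raise ValidationError("every grid dimension must be non-empty")

    def candidates(self) -> list[dict]:
        """Deterministically ordered list of hyperparameter dicts."""
        out = []
        for nr, md, eta, ss in itertools.product(
            self.num_round, self.max_depth, self.eta, self.subsample
        ):
            out.append(
                {"num_round": nr, "max_depth": md, "eta": eta, "subsample": ss}
            )
        return out

    def __len__(self) -> int:
        return (
            len(self.num_round) * len(self.max_depth) * len(self.eta) * len(self.subsample)
        )


def _xgb_params(hyper: dict, monotone: Optional[Sequence[int]], seed: int) -> dict:
    params = {
        "n_estimators": int(hyper.get("num_round", 100)),
        "max_depth": int(hyper.get("max_depth", 3)),
        "learning_rate": float(hyper.get("eta", 0.1)),
        "subsample": float(hyper.get("subsample", 1.0)),
        "colsample_bytree": float(hyper.get("subsample", 1.0)),
        "colsample_bylevel": float(hyper.get("subsample", 1.0)),
        "random_state": int(seed),
        "n_jobs": 1,
        "tree_method": "exact",
    }
    if monotone is not None:
        params["monotone_constraints"] = tuple(int(s) for s in monotone)
    return params


class MonotoneBoostedClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted logistic classifier with monotone constraints.

    Parameters mirror the tuned grid (``num_round``, ``max_depth``, ``eta``,
    ``subsample``); ``monotone`` is a per-feature sign sequence (+1/-1/0).
    """

    def __init__(
        self,
        num_round: int = 100,
        max_depth: int = 3,
        eta: float = 0.1,
        subsample: float = 1.0,
        monotone: Optional[tuple[int, ...]] = None,
        random_state: int = 0,
    ):
        self.num_round = num_round
        self.max_depth = max_depth
        self.eta = eta
        self.subsample = subsample
        self.monotone = monotone
        self.random_state = random_state

    def _hyper(self) -> dict:
        return {
            "num_round": self.num_round,
            "max_depth": self.max_depth,
            "eta": self.eta,
            "subsample": self.subsample,
        }

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size < 2:
            raise ValidationError(
                "training labels contain a single class; cannot fit a classifier"
            )
        self.classes_ = classes
        model = xgb.XGBClassifier(
            objective="binary:logistic",
            **_xgb_params(self._hyper(), self.monotone, self.random_state),
        )
        model.fit(X, y)
        self.booster_ = model.get_booster()
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_booster(cls, booster: xgb.Booster, **params) -> "MonotoneBoostedClassifier":
        """Rehydrate a fitted classifier from a persisted booster."""
        obj = cls(**params)
        obj.booster_ = booster
        obj.classes_ = np.array([0, 1])
        obj.n_features_in_ = booster.num_features()
        return obj

    def predict_proba(self, X):
        check_is_fitted(self, "booster_")
        p1 = self.booster_.predict(xgb.DMatrix(np.asarray(X, dtype=float)))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def get_booster(self) -> xgb.Booster:
        check_is_fitted(self, "booster_")
        return self.booster_


class MonotoneBoostedRegressor(BaseEstimator, RegressorMixin):
    """Gradient-boosted regressor optimized for mean absolute error."""

    def __init__(
        self,
        num_round: int = 100,
        max_depth: int = 3,
        eta: float = 0.1,
        subsample: float = 1.0,
        monotone: Optional[tuple[int, ...]] = None,
        random_state: int = 0,
    ):
        self.num_round = num_round
        self.max_depth = max_depth
        self.eta = eta
        self.subsample = subsample
        self.monotone = monotone
        self.random_state = random_state

    def _hyper(self) -> dict:
        return {
            "num_round": self.num_round,
            "max_depth": self.max_depth,
            "eta": self.eta,
            "subsample": self.subsample,
        }

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        model = xgb.XGBRegressor(
            objective="reg:absoluteerror",
            **_xgb_params(self._hyper(), self.monotone, self.random_state),
        )
        model.fit(X, y)
        self.booster_ = model.get_booster()
        self.n_features_in_ = X.shape[1]
        return self

    @classmethod
    def from_booster(cls, booster: xgb.Booster, **params) -> "MonotoneBoostedRegressor":
        """Rehydrate a fitted regressor from a persisted booster."""
        obj = cls(**params)
        obj.booster_ = booster
        obj.n_features_in_ = booster.num_features()
        return obj

    def predict(self, X):
        check_is_fitted(self, "booster_")
        pred = self.booster_.predict(xgb.DMatrix(np.asarray(X, dtype=float)))
        return np.asarray(pred, dtype=float)

    def get_booster(self) -> xgb.Booster:
        check_is_fitted(self, "booster_")
        return self.booster_


def train_classifier(
    X, y, hyper: dict, monotone: Optional[Sequence[int]] = None, seed: int = 0
) -> MonotoneBoostedClassifier:
    """Fit one classifier with explicit hyperparameters (functional wrapper)."""
    clf = MonotoneBoostedClassifier(
        monotone=None if monotone is None else tuple(monotone),
        random_state=seed,
        **hyper,
    )
    return clf.fit(X, y)


def train_regressor(
    X, y, hyper: dict, monotone: Optional[Sequence[int]] = None, seed: int = 0
) -> MonotoneBoostedRegressor:
    """Fit one MAE regressor with explicit hyperparameters."""
    reg = MonotoneBoostedRegressor(
        monotone=None if monotone is None else tuple(monotone),
        random_state=seed,
        **hyper,
    )
    return reg.fit(X, y)
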