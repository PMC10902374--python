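"""Dimensionally-weighted K-nearest-neighbor baseline (K = 20).

A deliberately simple reference model for the gradient-boosted predictor:
the ctDNA-fraction point prediction is the median label of the K nearest
training patients under a weighted Euclidean distance, and the probability
of ctDNA >= 2% is the fraction of those neighbors at or above 2%. Missing
input dimensions are simply omitted from the distance. The per-dimension
weights are learned by Nelder-Mead (derivative-free simplex) minimization of
the leave-one-out mean absolute error on the training set.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.metrics import roc_auc_score
from sklearn.utils.validation import check_is_fitted

from .boosting import SUFFICIENCY_THRESHOLD
from .errors import ValidationError
from .types import CohortTable

__all__ = ["DimensionallyWeightedKNN", "weighted_knn_baseline"]


class DimensionallyWeightedKNN(BaseEstimator):
    """KNN regressor/classifier with learned non-negative dimension weights.

    Features are internally standardized (training std = 1) so the simplex
    starts from comparable scales; weights are parameterized as squares of
    the optimizer's variables to enforce non-negativity. If the optimizer
    produces non-finite values it restarts from a perturbed simplex, up to
    ``max_restarts`` times.

    Attributes (after fit)
    ----------------------
    weights_ : per-dimension non-negative weights (on the scaled features)
    loo_mae_ : leave-one-out mean absolute error of the fraction prediction
    loo_auc_ : leave-one-out AUC of the sufficiency probability
    """

    def __init__(
        self,
        n_neighbors: int = 20,
        threshold: float = SUFFICIENCY_THRESHOLD,
        optimize_weights: bool = True,
        max_restarts: int = 3,
        maxiter: Optional[int] = None,
        random_state: int = 0,
    ):
        self.n_neighbors = n_neighbors
        self.threshold = threshold
        self.optimize_weights = optimize_weights
        self.max_restarts = max_restarts
        self.maxiter = maxiter
        self.random_state = random_state

    # -- distances ---------------------------------------------------------
    @staticmethod
    def _sq_diffs(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pairwise per-dimension squared differences and shared-dim masks."""
        diff = A[:, None, :] - B[None, :, :]
        shared = ~np.isnan(diff)
        return np.where(shared, diff, 0.0) ** 2, shared

    def _loo_predictions(self, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d2 = np.einsum("ijd,d->ij", self._sq_, weights)
        np.fill_diagonal(d2, np.inf)
        k = min(self.n_neighbors, d2.shape[0] - 1)
        idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
        labels = self._y_[idx]
        return np.median(labels, axis=1), (labels >= self.threshold).mean(axis=1)

    def _loo_mae(self, raw: np.ndarray) -> float:
        w = raw**2
        if not np.isfinite(w).all():
            return np.inf
        pred, _ = self._loo_predictions(w)
        return float(np.mean(np.abs(pred - self._y_)))

    def fit(self, X, y):
        X = np.asarray(
            X.data.to_numpy(dtype=float) if isinstance(X, CohortTable) else X,
            dtype=float,
        )
        y = np.asarray(y, dtype=float)
        n, d = X.shape
        if n <= self.n_neighbors:
            raise ValidationError(
                f"need more than n_neighbors={self.n_neighbors} rows, got {n}"
            )
        scale = np.array([np.nanstd(X[:, j], ddof=0) for j in range(d)])
        scale[~np.isfinite(scale) | (scale == 0.0)] = 1.0
        self.scale_ = scale
        self._X_ = X / scale
        self._y_ = y
        self._sq_, _ = self._sq_diffs(self._X_, self._X_)

        if self.optimize_weights:
            # the LOO objective is piecewise constant in the weights
            # (neighbor sets change discretely), so a single simplex can
            # stall on a plateau: run a few perturbed starts and keep the
            # best; non-finite outcomes trigger a fresh perturbed start too
            rng = np.random.default_rng(self.random_state)
            best = None
            x0 = np.ones(d)
            for attempt in range(self.max_restarts + 1):
                res = minimize(
                    self._loo_mae,
                    x0,
                    method="Nelder-Mead",
                    options={
                        "maxiter": self.maxiter or 200 * d,
                        "xatol": 1e-4,
                        "fatol": 1e-6,
                    },
                )
                if np.isfinite(res.fun) and np.isfinite(res.x).all():
                    if best is None or res.fun < best.fun:
                        best = res
                    x0 = best.x + 0.5 * rng.standard_normal(d)
                else:
                    x0 = np.ones(d) + 0.25 * rng.standard_normal(d)
            if best is None:
                raise ValidationError(
                    "weight optimization produced non-finite values after "
                    f"{self.max_restarts} restarts"
                )
            self.weights_ = best.x**2
        else:
            self.weights_ = np.ones(d)

        loo_pred, loo_prob = self._loo_predictions(self.weights_)
        self.loo_mae_ = float(np.mean(np.abs(loo_pred - y)))
        y_cls = (y >= self.threshold).astype(int)
        self.loo_auc_ = (
            float(roc_auc_score(y_cls, loo_prob))
            if np.unique(y_cls).size == 2
            else float("nan")
        )
        self.n_features_in_ = d
        return self

    def _neighbor_labels(self, X) -> np.ndarray:
        check_is_fitted(self, "weights_")
        X = np.asarray(
            X.data.to_numpy(dtype=float) if isinstance(X, CohortTable) else X,
            dtype=float,
        )
        sq, shared = self._sq_diffs(X / self.scale_, self._X_)
        if not shared.any(axis=(1, 2)).all():
            bad = int(np.argmin(shared.any(axis=(1, 2))))
            raise ValidationError(f"row {bad} shares no observed dimension")
        d2 = np.einsum("ijd,d->ij", sq, self.weights_)
        k = min(self.n_neighbors, d2.shape[1])
        idx = np.argpartition(d2, k - 1, axis=1)[:, :k]
        return self._y_[idx]

    def predict(self, X) -> np.ndarray:
        """Median ctDNA fraction of the K nearest training patients."""
        return np.median(self._neighbor_labels(X), axis=1)

    def predict_proba(self, X) -> np.ndarray:
        """P(ctDNA >= threshold) = fraction of neighbors at/above it."""
        p1 = (self._neighbor_labels(X) >= self.threshold).mean(axis=1)
        return np.column_stack([1.0 - p1, p1])


def weighted_knn_baseline(
    table: CohortTable, k: int = 20, seed: int = 0, **kwargs
) -> tuple[DimensionallyWeightedKNN, dict]:
    """Fit the baseline on a labelled cohort; returns (model, LOO report)."""
    if table.label is None:
        raise ValidationError("cohort has no ctDNA-fraction labels")
    labelled = table.label.notna()
    model = DimensionallyWeightedKNN(n_neighbors=k, random_state=seed, **kwargs).fit(
        table.data.loc[labelled], table.label.loc[labelled].to_numpy(dtype=float)
    )
    report = {
        "loo_mae": model.loo_mae_,
        "loo_auc": model.loo_auc_,
        "weights": dict(zip(table.feature_names, model.weights_)),
        "n": int(labelled.sum()),
        "k": k,
    }
    return model, report
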