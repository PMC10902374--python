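"""K-nearest-neighbor imputation against a reference cohort.

Scaling statistics (per-dimension standard deviation) come from the
reference only, so imputing a validation fold never leaks its own
distribution. Distances are root-mean-square differences over the
dimensions observed in both rows; each missing cell is filled with the mean
(continuous) or mode (binary/categorical) of the K nearest reference rows
that observe that feature. Observed cells are never touched.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .types import CohortTable, FeatureSpec

__all__ = ["CohortKNNImputer", "knn_impute"]


class CohortKNNImputer(BaseEstimator, TransformerMixin):
    """Impute missing clinical values from the K nearest reference patients.

    Parameters
    ----------
    n_neighbors : int, default 3
        Number of reference rows averaged per missing cell.

    Attributes (after fit)
    ----------------------
    scale_ : ndarray of shape (n_features,)
        Per-feature standard deviation on the reference (1 where degenerate).
    reference_ : ndarray of shape (n_reference, n_features)
        Raw reference matrix (NaN where missing).
    feature_specs_ : dict[str, FeatureSpec] or None
        Feature declarations when fitted from a CohortTable (drives the
        mean-vs-mode imputed statistic).
    """

    def __init__(self, n_neighbors: int = 3):
        self.n_neighbors = n_neighbors

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _as_matrix(table) -> tuple[np.ndarray, Optional[dict[str, FeatureSpec]]]:
        if isinstance(table, CohortTable):
            return table.data.to_numpy(dtype=float), table.features
        if isinstance(table, pd.DataFrame):
            return table.to_numpy(dtype=float), None
        return np.asarray(table, dtype=float), None

    def fit(self, X, y=None):
        if self.n_neighbors < 1:
            raise ValidationError("n_neighbors must be >= 1")
        ref, specs = self._as_matrix(X)
        if ref.ndim != 2 or ref.shape[0] == 0:
            raise ValidationError("reference must be a non-empty 2-D table")
        all_missing = np.isnan(ref).all(axis=0)
        if all_missing.any():
            raise ValidationError(
                f"reference column {int(np.argmax(all_missing))} is entirely missing"
            )
        scale = np.array(
            [np.nanstd(ref[:, j], ddof=0) for j in range(ref.shape[1])]
        )
        scale[~np.isfinite(scale) | (scale == 0.0)] = 1.0
        self.scale_ = scale
        self.reference_ = ref
        self.feature_specs_ = specs
        self.n_features_in_ = ref.shape[1]
        return self

    def _impute_matrix(self, X: np.ndarray) -> np.ndarray:
        ref = self.reference_ / self.scale_
        out = X.copy()
        Xs = X / self.scale_
        kinds = None
        if self.feature_specs_ is not None:
            kinds = [s.kind for s in self.feature_specs_.values()]
        for i in range(X.shape[0]):
            row = Xs[i]
            missing = np.isnan(row)
            if not missing.any():
                continue
            observed = ~missing
            shared = observed[None, :] & ~np.isnan(ref)
            n_shared = shared.sum(axis=1)
            usable = n_shared > 0
            if not usable.any():
                raise ValidationError(
                    f"row {i} shares no observed dimension with any reference row"
                )
            diff = np.where(shared, ref - row[None, :], 0.0)
            # root-mean-square over shared dims keeps rows with different
            # numbers of shared dimensions comparable
            dist = np.sqrt((diff**2).sum(axis=1) / np.maximum(n_shared, 1))
            dist[~usable] = np.inf
            order = np.argsort(dist, kind="stable")
            for j in np.flatnonzero(missing):
                donors = order[~np.isnan(self.reference_[order, j])]
                donors = donors[np.isfinite(dist[donors])]
                if donors.size == 0:
                    raise ValidationError(
                        f"no reference row observes feature {j} within reach of row {i}"
                    )
                take = donors[: self.n_neighbors]
                values = self.reference_[take, j]
                if kinds is not None and kinds[j] in ("binary", "categorical"):
                    levels, counts = np.unique(values, return_counts=True)
                    out[i, j] = levels[np.argmax(counts)]
                else:
                    out[i, j] = float(values.mean())
        return out

    def transform(self, X):
        check_is_fitted(self, "reference_")
        if isinstance(X, CohortTable):
            filled = self._impute_matrix(X.data.to_numpy(dtype=float))
            frame = pd.DataFrame(filled, index=X.data.index, columns=X.data.columns)
            return CohortTable(
                data=frame, features=dict(X.features), label=X.label
            )
        if isinstance(X, pd.DataFrame):
            filled = self._impute_matrix(X.to_numpy(dtype=float))
            return pd.DataFrame(filled, index=X.index, columns=X.columns)
        return self._impute_matrix(np.asarray(X, dtype=float))


def knn_impute(table: CohortTable, reference: CohortTable, k: int = 3) -> CohortTable:
    """Impute ``table`` using ``reference`` rows (K=3, sd-1 scaling on the
    reference). Functional wrapper over :class:`CohortKNNImputer`."""
    return CohortKNNImputer(n_neighbors=k).fit(reference).transform(table)
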