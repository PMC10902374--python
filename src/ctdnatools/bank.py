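"""Per-missing-pattern model bank for point-of-care sufficiency prediction.

Users of a bedside prediction tool rarely have every clinical variable at
hand. Rather than imputing absent inputs at prediction time (which would
make sparse queries depend mostly on the imputation algorithm), one
classification model and one MAE regression model are trained for every
non-empty subset of the declared features — ``2^k - 1`` patterns, 255 for
the default 8-variable panel. A query is routed to the pair whose pattern
exactly matches its observed features, so prediction never imputes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import xgboost as xgb
import yaml
from sklearn.base import BaseEstimator

from .boosting import (
    HyperGrid,
    MonotoneBoostedClassifier,
    MonotoneBoostedRegressor,
    SUFFICIENCY_THRESHOLD,
)
from .errors import ValidationError
from .impute import CohortKNNImputer
from .tuning import adaptive_grid_search
from .types import CohortTable

__all__ = [
    "MissingPatternBank",
    "SufficiencyPrediction",
    "train_missing_pattern_bank",
    "predict_sufficiency",
]

DEFAULT_CLASSIFIER_HYPER = {
    "num_round": 100, "max_depth": 3, "eta": 0.05, "subsample": 0.75,
}
DEFAULT_REGRESSOR_HYPER = {
    "num_round": 100, "max_depth": 2, "eta": 0.05, "subsample": 0.75,
}

MAX_BANK_FEATURES = 12


@dataclass(frozen=True)
class SufficiencyPrediction:
    """Bank output for one patient record."""

    probability: float  # P(ctDNA >= 2%)
    fraction: float  # point estimate of ctDNA fraction, clipped to [0,1]
    pattern: str  # bitmask over the declared feature order, '1' = observed
    features_used: tuple[str, ...]


def _pattern_id(features: Sequence[str], observed: Sequence[str]) -> str:
    observed = set(observed)
    return "".join("1" if f in observed else "0" for f in features)


class MissingPatternBank(BaseEstimator):
    """Family of paired classification/regression models, one per pattern.

    Parameters
    ----------
    features : sequence of str, optional
        Declared feature panel (defaults to the cohort's columns at fit
        time). At most 12 features (bank size 2^k - 1 must stay tractable).
    classifier_hyper, regressor_hyper : dict, optional
        Explicit hyperparameters used for every pattern.
    grid : HyperGrid, optional
        When given, hyperparameters are tuned by adaptive grid search; with
        ``tune="shared"`` (default) tuning runs once on the full-feature
        pattern and the winners are reused bank-wide, with
        ``tune="per_pattern"`` each pattern is tuned independently.
    threshold : float
        ctDNA-fraction cutoff defining the classification label (>= 2%).
    """

    def __init__(
        self,
        features: Optional[Sequence[str]] = None,
        classifier_hyper: Optional[dict] = None,
        regressor_hyper: Optional[dict] = None,
        grid: Optional[HyperGrid] = None,
        tune: str = "shared",
        inner_folds: int = 5,
        threshold: float = SUFFICIENCY_THRESHOLD,
        imputer_k: int = 3,
        random_state: int = 0,
    ):
        self.features = features
        self.classifier_hyper = classifier_hyper
        self.regressor_hyper = regressor_hyper
        self.grid = grid
        self.tune = tune
        self.inner_folds = inner_folds
        self.threshold = threshold
        self.imputer_k = imputer_k
        self.random_state = random_state

    def fit(self, table: CohortTable, y=None):
        if table.label is None:
            raise ValidationError("cohort has no ctDNA-fraction labels")
        feats = table.feature_names if self.features is None else list(self.features)
        if len(feats) == 0:
            raise ValidationError("need at least one feature")
        if len(feats) > MAX_BANK_FEATURES:
            raise ValidationError(
                f"{len(feats)} features would require {2 ** len(feats) - 1} "
                f"model pairs; cap is {MAX_BANK_FEATURES} features"
            )
        missing = set(feats) - set(table.feature_names)
        if missing:
            raise ValidationError(f"features not in cohort: {sorted(missing)}")

        labelled = table.label.notna()
        y_frac = table.label.loc[labelled].to_numpy(dtype=float)
        y_cls = (y_frac >= self.threshold).astype(int)
        if np.unique(y_cls).size < 2:
            raise ValidationError("labels contain a single sufficiency class")

        # one self-referenced imputation over the whole cohort panel (all
        # declared columns give imputation context); pattern models then see
        # complete columns restricted to their subset
        all_data = table.data.loc[labelled]
        imputer = CohortKNNImputer(n_neighbors=self.imputer_k).fit(all_data)
        imputed = imputer.transform(all_data)
        X_full = imputed[feats].to_numpy(dtype=float)
        signs = {f: table.features[f].monotone for f in feats}

        clf_hyper = dict(self.classifier_hyper or DEFAULT_CLASSIFIER_HYPER)
        reg_hyper = dict(self.regressor_hyper or DEFAULT_REGRESSOR_HYPER)
        if self.grid is not None and self.tune == "shared":
            mono = tuple(signs[f] for f in feats)
            clf_hyper, _ = adaptive_grid_search(
                X_full, y_cls, grid=self.grid, inner_folds=self.inner_folds,
                seed=self.random_state, task="classify", monotone=mono,
            )
            reg_hyper, _ = adaptive_grid_search(
                X_full, y_frac, grid=self.grid, inner_folds=self.inner_folds,
                seed=self.random_state, task="regress", monotone=mono,
            )

        self.feature_names_ = feats
        self.monotone_map_ = signs
        self.classifier_hyper_ = clf_hyper
        self.regressor_hyper_ = reg_hyper
        self.models_: dict[str, tuple[MonotoneBoostedClassifier, MonotoneBoostedRegressor]] = {}

        col_index = {f: j for j, f in enumerate(feats)}
        for r in range(1, len(feats) + 1):
            for subset in itertools.combinations(feats, r):
                cols = [col_index[f] for f in subset]
                X = X_full[:, cols]
                mono = tuple(signs[f] for f in subset)
                c_hyper, r_hyper = clf_hyper, reg_hyper
                if self.grid is not None and self.tune == "per_pattern":
                    c_hyper, _ = adaptive_grid_search(
                        X, y_cls, grid=self.grid, inner_folds=self.inner_folds,
                        seed=self.random_state, task="classify", monotone=mono,
                    )
                    r_hyper, _ = adaptive_grid_search(
                        X, y_frac, grid=self.grid, inner_folds=self.inner_folds,
                        seed=self.random_state, task="regress", monotone=mono,
                    )
                clf = MonotoneBoostedClassifier(
                    monotone=mono, random_state=self.random_state, **c_hyper
                ).fit(X, y_cls)
                reg = MonotoneBoostedRegressor(
                    monotone=mono, random_state=self.random_state, **r_hyper
                ).fit(X, y_frac)
                self.models_[_pattern_id(feats, subset)] = (clf, reg)
        return self

    # -- prediction --------------------------------------------------------
    @property
    def n_patterns_(self) -> int:
        return len(self.models_)

    def _observed_features(self, record) -> list[str]:
        if isinstance(record, pd.Series):
            record = record.to_dict()
        observed = []
        for f in self.feature_names_:
            v = record.get(f)
            if v is None:
                continue
            v = float(v)
            if not np.isnan(v):
                observed.append(f)
        return observed

    def predict_record(self, record) -> SufficiencyPrediction:
        """Predict for one partially-observed patient record (dict/Series)."""
        observed = self._observed_features(record)
        if not observed:
            raise ValidationError(
                "all declared features are missing; provide at least one of: "
                + ", ".join(self.feature_names_)
            )
        pattern = _pattern_id(self.feature_names_, observed)
        clf, reg = self.models_[pattern]
        if isinstance(record, pd.Series):
            record = record.to_dict()
        x = np.array([[float(record[f]) for f in observed]])
        prob = float(clf.predict_proba(x)[0, 1])
        frac = float(np.clip(reg.predict(x)[0], 0.0, 1.0))
        return SufficiencyPrediction(
            probability=prob,
            fraction=frac,
            pattern=pattern,
            features_used=tuple(observed),
        )

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Row-wise bank predictions for a feature frame with NaN gaps."""
        rows = []
        for pid, row in X.iterrows():
            p = self.predict_record(row)
            rows.append(
                {
                    "patient_id": pid,
                    "pattern": p.pattern,
                    "p_ge_2pct": p.probability,
                    "predicted_fraction": p.fraction,
                }
            )
        return pd.DataFrame(rows).set_index("patient_id")

    # -- persistence -------------------------------------------------------
    def save(self, directory: Union[str, Path]) -> None:
        """Write manifest.yaml plus one JSON model file per pattern-model."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {
            "features": self.feature_names_,
            "monotone_map": self.monotone_map_,
            "threshold": self.threshold,
            "classifier_hyper": self.classifier_hyper_,
            "regressor_hyper": self.regressor_hyper_,
            "random_state": self.random_state,
            "patterns": sorted(self.models_),
        }
        with open(directory / "manifest.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh)
        for pattern, (clf, reg) in self.models_.items():
            clf.get_booster().save_model(str(directory / f"clf_{pattern}.json"))
            reg.get_booster().save_model(str(directory / f"reg_{pattern}.json"))

    @classmethod
    def load(cls, directory: Union[str, Path]) -> "MissingPatternBank":
        directory = Path(directory)
        with open(directory / "manifest.yaml", "r", encoding="utf-8") as fh:
            manifest = yaml.safe_load(fh)
        bank = cls(
            features=manifest["features"],
            classifier_hyper=manifest["classifier_hyper"],
            regressor_hyper=manifest["regressor_hyper"],
            threshold=manifest["threshold"],
            random_state=manifest["random_state"],
        )
        bank.feature_names_ = list(manifest["features"])
        bank.monotone_map_ = dict(manifest["monotone_map"])
        bank.classifier_hyper_ = dict(manifest["classifier_hyper"])
        bank.regressor_hyper_ = dict(manifest["regressor_hyper"])
        bank.models_ = {}
        for pattern in manifest["patterns"]:
            cb = xgb.Booster()
            cb.load_model(str(directory / f"clf_{pattern}.json"))
            rb = xgb.Booster()
            rb.load_model(str(directory / f"reg_{pattern}.json"))
            bank.models_[pattern] = (
                MonotoneBoostedClassifier.from_booster(cb, **bank.classifier_hyper_),
                MonotoneBoostedRegressor.from_booster(rb, **bank.regressor_hyper_),
            )
        return bank


def train_missing_pattern_bank(
    table: CohortTable,
    features: Optional[Sequence[str]] = None,
    grid: Optional[HyperGrid] = None,
    seed: int = 0,
    **kwargs,
) -> MissingPatternBank:
    """Train the full bank on a labelled cohort (functional wrapper)."""
    return MissingPatternBank(
        features=features, grid=grid, random_state=seed, **kwargs
    ).fit(table)


def predict_sufficiency(bank: MissingPatternBank, record) -> SufficiencyPrediction:
    """Route one record to its exact-pattern model pair; never imputes."""
    return bank.predict_record(record)
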