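"""Adaptive hyperparameter search and nested cross-validated evaluation.

The search is a successive-halving grid search: every surviving candidate is
scored on *identical* inner-fold splits (so candidate ranking is never
affected by split sampling), the bottom half is eliminated each iteration,
and the number of cross-validation repetitions doubles for the survivors —
ranking precision grows as the field narrows. Generalization accuracy is
measured by nested cross-validation: hyperparameters are tuned inside each
outer training fold, and the outer test fold — imputed with the training
fold as its only reference — is scored exactly once.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold

from .boosting import (
    HyperGrid,
    MonotoneBoostedClassifier,
    MonotoneBoostedRegressor,
    SUFFICIENCY_THRESHOLD,
)
from .errors import ValidationError
from .impute import CohortKNNImputer
from .types import CohortTable

__all__ = [
    "halving_schedule",
    "adaptive_grid_search",
    "nested_cv_evaluate",
    "PerformanceReport",
]


def halving_schedule(n_candidates: int) -> list[int]:
    """Survivor counts of the 50%-elimination schedule, starting at n.

    Each round keeps ``ceil(n/2)`` candidates (ties broken by candidate
    order), e.g. 630 -> 315 -> 158 -> 79 -> ... -> 1.
    """
    if n_candidates < 1:
        raise ValidationError("need at least one candidate")
    counts = [n_candidates]
    while counts[-1] > 1:
        counts.append(math.ceil(counts[-1] / 2))
    return counts


def _fold_auc(model, X_val, y_val) -> float:
    if np.unique(y_val).size < 2:
        return np.nan
    return roc_auc_score(y_val, model.predict_proba(X_val)[:, 1])


def adaptive_grid_search(
    X,
    y,
    grid: Union[HyperGrid, Sequence[dict]] = HyperGrid(),
    inner_folds: int = 5,
    seed: int = 0,
    task: str = "classify",
    monotone: Optional[Sequence[int]] = None,
    max_repetitions: int = 16,
) -> tuple[dict, list[dict]]:
    """Successive-halving search over the hyperparameter grid.

    Iteration ``r`` evaluates all surviving candidates on identical
    ``inner_folds``-fold splits repeated ``R_r`` times (``R_1 = 1``, doubling
    each iteration, capped at ``max_repetitions``), ranks by mean AUC
    (classification) or mean negative MAE (regression) across folds, and
    drops the bottom half. Returns the winning hyperparameter dict and a
    per-iteration trace of survivor counts.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) < inner_folds:
        raise ValidationError(
            f"{len(y)} labelled rows but {inner_folds} inner folds requested"
        )
    candidates = grid.candidates() if isinstance(grid, HyperGrid) else list(grid)
    if not candidates:
        raise ValidationError("empty hyperparameter grid")

    survivors = list(range(len(candidates)))
    trace: list[dict] = []
    if len(survivors) == 1:
        return dict(candidates[0]), [
            {"iteration": 1, "n_candidates": 1, "repetitions": 0, "scores": [np.nan]}
        ]

    split_cache: list[list[tuple[np.ndarray, np.ndarray]]] = []

    def splits_for(rep_index: int):
        while len(split_cache) <= rep_index:
            kf = KFold(
                n_splits=inner_folds,
                shuffle=True,
                random_state=(seed * 131 + len(split_cache)) % (2**31 - 1),
            )
            split_cache.append(list(kf.split(X)))
        return split_cache[rep_index]

    def score_candidate(hyper: dict, repetitions: int) -> float:
        fold_scores: list[float] = []
        for r in range(repetitions):
            for train_idx, val_idx in splits_for(r):
                y_tr = y[train_idx]
                if task == "classify":
                    if np.unique(y_tr).size < 2:
                        continue
                    model = MonotoneBoostedClassifier(
                        monotone=None if monotone is None else tuple(monotone),
                        random_state=seed,
                        **hyper,
                    ).fit(X[train_idx], y_tr)
                    s = _fold_auc(model, X[val_idx], y[val_idx].astype(int))
                else:
                    model = MonotoneBoostedRegressor(
                        monotone=None if monotone is None else tuple(monotone),
                        random_state=seed,
                        **hyper,
                    ).fit(X[train_idx], y_tr)
                    s = -float(np.mean(np.abs(model.predict(X[val_idx]) - y[val_idx])))
                if not np.isnan(s):
                    fold_scores.append(float(s))
        return float(np.mean(fold_scores)) if fold_scores else -np.inf

    repetitions = 1
    iteration = 0
    while True:
        iteration += 1
        scored = [
            (score_candidate(candidates[i], repetitions), i) for i in survivors
        ]
        # higher score first; ties resolved by original candidate order
        ranked = sorted(scored, key=lambda si: (-si[0], si[1]))
        trace.append(
            {
                "iteration": iteration,
                "n_candidates": len(survivors),
                "repetitions": repetitions,
                "best_score": ranked[0][0],
            }
        )
        if len(survivors) == 1 or repetitions >= max_repetitions:
            best = ranked[0][1]
            return dict(candidates[best]), trace
        keep = math.ceil(len(survivors) / 2)
        survivors = [i for _, i in ranked[:keep]]
        if len(survivors) == 1:
            trace.append(
                {
                    "iteration": iteration + 1,
                    "n_candidates": 1,
                    "repetitions": repetitions,
                    "best_score": ranked[0][0],
                }
            )
            return dict(candidates[survivors[0]]), trace
        repetitions = min(repetitions * 2, max_repetitions)


@dataclass
class PerformanceReport:
    """Nested-CV performance summary for the sufficiency classifier."""

    n: int
    outer_folds: int
    pooled_auc: float
    per_fold_auc: list[float]
    ppv: float
    npv: float
    confusion: dict[str, int]
    fold_assignments: list[list[int]]
    chosen_hyper: list[dict]
    state_hash: str
    mae: Optional[float] = None
    seed: int = 0

    def to_json(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items()
        }
        return json.dumps(payload, indent=2, default=float)


def nested_cv_evaluate(
    table: CohortTable,
    grid: Union[HyperGrid, Sequence[dict]] = HyperGrid(),
    outer_folds: int = 20,
    inner_folds: int = 5,
    seed: int = 0,
    threshold: float = SUFFICIENCY_THRESHOLD,
    evaluate_regression: bool = False,
    imputer_k: int = 3,
) -> PerformanceReport:
    """Nested cross-validation of the sufficiency classifier.

    Per outer fold: the training fold is imputed against itself, the test
    fold against the training fold only (no leakage of test statistics);
    hyperparameters are tuned on the training fold via
    :func:`adaptive_grid_search`; the fitted model scores the test fold.
    ``state_hash`` digests the per-fold imputed training matrices, imputer
    scaling statistics and chosen hyperparameters — anything downstream of
    the outer-test labels is excluded, so perturbing test labels must leave
    it unchanged.
    """
    if outer_folds < 2:
        raise ValidationError("outer_folds must be >= 2")
    if table.label is None:
        raise ValidationError("cohort has no ctDNA-fraction labels")
    labelled = table.label.notna().to_numpy()
    data = table.data.loc[labelled]
    y_frac = table.label.loc[labelled].to_numpy(dtype=float)
    y = (y_frac >= threshold).astype(int)
    n = len(data)
    if n < outer_folds:
        raise ValidationError(f"{n} labelled rows < {outer_folds} outer folds")

    monotone = table.monotone_signs()
    kf = KFold(n_splits=outer_folds, shuffle=True, random_state=seed % (2**31 - 1))

    digest = hashlib.sha256()
    proba = np.full(n, np.nan)
    frac_pred = np.full(n, np.nan)
    per_fold_auc: list[float] = []
    fold_assignments: list[list[int]] = []
    chosen: list[dict] = []

    for fold, (train_idx, test_idx) in enumerate(kf.split(data)):
        fold_seed = (seed * 100003 + fold * 7919) % (2**31 - 1)
        imputer = CohortKNNImputer(n_neighbors=imputer_k).fit(
            data.iloc[train_idx]
        )
        X_train = np.asarray(imputer.transform(data.iloc[train_idx]))
        X_test = np.asarray(imputer.transform(data.iloc[test_idx]))

        hyper, _ = adaptive_grid_search(
            X_train,
            y[train_idx],
            grid=grid,
            inner_folds=inner_folds,
            seed=fold_seed,
            task="classify",
            monotone=monotone,
        )
        digest.update(X_train.tobytes())
        digest.update(np.asarray(imputer.scale_).tobytes())
        digest.update(json.dumps(hyper, sort_keys=True).encode())

        clf = MonotoneBoostedClassifier(
            monotone=monotone, random_state=fold_seed, **hyper
        ).fit(X_train, y[train_idx])
        proba[test_idx] = clf.predict_proba(X_test)[:, 1]
        per_fold_auc.append(_fold_auc(clf, X_test, y[test_idx]))
        fold_assignments.append([int(i) for i in test_idx])
        chosen.append(hyper)

        if evaluate_regression:
            reg_hyper, _ = adaptive_grid_search(
                X_train,
                y_frac[train_idx],
                grid=grid,
                inner_folds=inner_folds,
                seed=fold_seed,
                task="regress",
                monotone=monotone,
            )
            reg = MonotoneBoostedRegressor(
                monotone=monotone, random_state=fold_seed, **reg_hyper
            ).fit(X_train, y_frac[train_idx])
            frac_pred[test_idx] = np.clip(reg.predict(X_test), 0.0, 1.0)

    pooled_auc = float(roc_auc_score(y, proba))
    pred = (proba >= 0.5).astype(int)
    tp = int(np.sum((pred == 1) & (y == 1)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    mae = (
        float(np.mean(np.abs(frac_pred - y_frac))) if evaluate_regression else None
    )

    return PerformanceReport(
        n=n,
        outer_folds=outer_folds,
        pooled_auc=pooled_auc,
        per_fold_auc=[float(a) for a in per_fold_auc],
        ppv=float(ppv),
        npv=float(npv),
        confusion={"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        fold_assignments=fold_assignments,
        chosen_hyper=chosen,
        state_hash=digest.hexdigest(),
        mae=mae,
        seed=seed,
    )
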