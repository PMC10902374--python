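"""Adaptive grid search and nested cross-validation integrity tests."""

import hashlib
import json

import numpy as np
import pytest

from ctdnatools import (
    CohortKNNImputer,
    HyperGrid,
    MonotoneBoostedClassifier,
    ValidationError,
    adaptive_grid_search,
    halving_schedule,
    nested_cv_evaluate,
)
from ctdnatools.simulate import CohortSimConfig, simulate_clinical_cohort

FAST = {"num_round": 10, "max_depth": 2, "eta": 0.1, "subsample": 0.75}


def null_cohort(n=200, seed=0, missing=0.0):
    return simulate_clinical_cohort(
        CohortSimConfig(
            n_patients=n, seed=seed, missing_rate=missing,
            loadings={f: 0.0 for f in CohortSimConfig().features},
        )
    )


class TestAdaptiveGridSearch:
    def test_halving_schedule_from_full_grid(self):
        """630 candidates shrink by ceil-half each round down to one."""
        assert len(HyperGrid()) == 630
        assert halving_schedule(630)[:5] == [630, 315, 158, 79, 40]
        assert halving_schedule(630)[-1] == 1

    def test_single_candidate_returned_immediately(self, rng):
        x = rng.random((50, 2))
        y = (x[:, 0] > 0.5).astype(int)
        hyper, trace = adaptive_grid_search(x, y, grid=[FAST], seed=0)
        assert hyper == FAST
        assert len(trace) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_dominant_candidate_wins_under_any_seed(self, seed):
        """Depth-1 trees cannot represent an XOR label; the deeper
        candidate dominates on every split."""
        r = np.random.default_rng(7)
        x = r.random((200, 2))
        y = ((x[:, 0] > 0.5) ^ (x[:, 1] > 0.5)).astype(int)
        shallow = {"num_round": 30, "max_depth": 1, "eta": 0.3, "subsample": 1.0}
        deep = {"num_round": 30, "max_depth": 3, "eta": 0.3, "subsample": 1.0}
        hyper, trace = adaptive_grid_search(x, y, grid=[shallow, deep], seed=seed)
        assert hyper == deep
        assert [t["n_candidates"] for t in trace] == [2, 1]

    def test_survivor_counts_follow_ceil_half(self, rng):
        x = rng.random((60, 2))
        y = (x[:, 0] > 0.5).astype(int)
        grid = [dict(FAST, num_round=n) for n in (5, 10, 15, 20, 25)]
        _, trace = adaptive_grid_search(x, y, grid=grid, seed=1)
        assert [t["n_candidates"] for t in trace] == [5, 3, 2, 1]

    def test_repetitions_double_each_iteration(self, rng):
        x = rng.random((60, 2))
        y = (x[:, 0] > 0.5).astype(int)
        grid = [dict(FAST, num_round=n) for n in (5, 10, 15, 20, 25)]
        _, trace = adaptive_grid_search(x, y, grid=grid, seed=1)
        reps = [t["repetitions"] for t in trace]
        assert reps[:3] == [1, 2, 4]

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValidationError, match="inner folds"):
            adaptive_grid_search(rng.random((3, 2)), np.array([0, 1, 0]),
                                 grid=[FAST, FAST], inner_folds=5)


class TestNestedCV:
    def test_folds_partition_rows(self, complete_cohort):
        report = nested_cv_evaluate(
            complete_cohort, grid=[FAST], outer_folds=10, seed=3
        )
        flat = sorted(i for fold in report.fold_assignments for i in fold)
        assert flat == list(range(complete_cohort.n_patients))
        sizes = [len(f) for f in report.fold_assignments]
        assert sum(sizes) == complete_cohort.n_patients
        assert report.confusion["tn"] + report.confusion["fp"] + \
            report.confusion["fn"] + report.confusion["tp"] == report.n

    def test_deterministic_given_seed(self, complete_cohort):
        a = nested_cv_evaluate(complete_cohort, grid=[FAST], outer_folds=5, seed=9)
        b = nested_cv_evaluate(complete_cohort, grid=[FAST], outer_folds=5, seed=9)
        assert a.pooled_auc == b.pooled_auc
        assert a.state_hash == b.state_hash
        assert a.per_fold_auc == b.per_fold_auc

    def test_state_hash_derives_from_training_folds_only(self, small_cohort):
        """Recomputing the imputation + tuning pipeline from the training
        rows alone reproduces the state hash exactly — nothing from the
        outer-test labels can have leaked into it."""
        grid = [FAST, dict(FAST, num_round=20)]
        report = nested_cv_evaluate(
            small_cohort, grid=grid, outer_folds=4, inner_folds=3, seed=5
        )
        labelled = small_cohort.label.notna().to_numpy()
        data = small_cohort.data.loc[labelled]
        y = (small_cohort.label.loc[labelled].to_numpy() >= 0.02).astype(int)
        digest = hashlib.sha256()
        n = len(data)
        all_rows = set(range(n))
        for fold, test_idx in enumerate(report.fold_assignments):
            train_idx = sorted(all_rows - set(test_idx))
            fold_seed = (5 * 100003 + fold * 7919) % (2**31 - 1)
            imputer = CohortKNNImputer(3).fit(data.iloc[train_idx])
            X_train = np.asarray(imputer.transform(data.iloc[train_idx]))
            hyper, _ = adaptive_grid_search(
                X_train, y[train_idx], grid=grid, inner_folds=3,
                seed=fold_seed, monotone=small_cohort.monotone_signs(),
            )
            digest.update(X_train.tobytes())
            digest.update(np.asarray(imputer.scale_).tobytes())
            digest.update(json.dumps(hyper, sort_keys=True).encode())
            assert hyper == report.chosen_hyper[fold]
        assert digest.hexdigest() == report.state_hash

    def test_null_cohort_auc_near_half(self):
        """Without planted signal the pooled AUC stays near chance."""
        aucs = [
            nested_cv_evaluate(
                null_cohort(n=200, seed=s), grid=[FAST], outer_folds=10, seed=s
            ).pooled_auc
            for s in range(10)
        ]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.08)

    def test_planted_signal_auc_high(self):
        strong = {
            "cfdna_conc": 0.8, "psa": 0.6, "ldh_uln": 0.6, "alp_uln": 0.5,
            "hemoglobin": -0.5, "liver_mets": 0.6, "bone_mets_10plus": 0.5,
            "ecog_2plus": 0.4,
        }
        table = simulate_clinical_cohort(
            CohortSimConfig(n_patients=400, seed=5, loadings=strong)
        )
        report = nested_cv_evaluate(
            table, grid=[dict(FAST, num_round=50, max_depth=3)],
            outer_folds=10, seed=6,
        )
        assert report.pooled_auc > 0.75

    def test_invalid_arguments(self, complete_cohort):
        with pytest.raises(ValidationError):
            nested_cv_evaluate(complete_cohort, grid=[FAST], outer_folds=1)
        unlabelled = complete_cohort.copy()
        unlabelled.label = None
        with pytest.raises(ValidationError, match="labels"):
            nested_cv_evaluate(unlabelled, grid=[FAST])
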