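"""Splits, multiclass metrics (vs brute-force oracles), DeLong, importance."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score

from ptmgan.classify_eval import (
    PipelineOptions,
    _auc_midrank,
    accuracy,
    aggregate_importance,
    cen,
    confusion,
    delong_test,
    error_rate,
    make_split,
    multiclass_mcc,
    per_class_metrics,
    run_pipeline_fold,
)


class TestSplit:
    def test_stratified_sizes_and_partition(self):
        labels = np.repeat([1, 2, 3], 100)
        plan = make_split(labels, seed=0, n_folds=10)
        assert len(plan.test_idx) == 60
        for cls in (1, 2, 3):
            assert (labels[plan.test_idx] == cls).sum() == 20
        union = np.sort(np.concatenate([v for _, v in plan.folds]))
        assert np.array_equal(union, plan.train_idx)

    def test_same_seed_identical_plan(self):
        labels = np.repeat([1, 2], 60)
        a = make_split(labels, seed=5)
        b = make_split(labels, seed=5)
        assert np.array_equal(a.test_idx, b.test_idx)
        assert all(np.array_equal(x[1], y[1]) for x, y in zip(a.folds, b.folds))

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_split(np.array([1] * 50 + [2] * 3), seed=0)


class TestOverallMetrics:
    def test_perfect_diagonal(self):
        cm = np.diag([5, 7, 9])
        assert accuracy(cm) == 1.0
        assert error_rate(cm) == 0.0
        assert multiclass_mcc(cm) == pytest.approx(1.0)
        assert cen(cm) == 0.0

    def test_error_rate_identity_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            cm = rng.integers(0, 30, (4, 4))
            cm[0, 0] += 1
            assert error_rate(cm) == pytest.approx(1 - accuracy(cm), abs=1e-12)

    def test_uniform_confusion_mcc_zero(self):
        assert multiclass_mcc(np.full((7, 7), 3)) == pytest.approx(0.0)

    def test_mcc_reduces_to_binary_formula(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fn, fp, tn = rng.integers(1, 40, 4)
            cm = np.array([[tp, fn], [fp, tn]])
            den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
            expected = (tp * tn - fp * fn) / den
            assert multiclass_mcc(cm) == pytest.approx(expected, abs=1e-12)

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((3, 3), dtype=int))


def _cen_bruteforce(cm):
    """Independent term-by-term confusion-entropy summation."""
    cm = np.asarray(cm, dtype=float)
    K = cm.shape[0]
    N = cm.sum()
    total = 0.0
    for j in range(K):
        denom = sum(cm[j, k] + cm[k, j] for k in range(K))
        if denom == 0:
            continue
        w = denom / (2 * N)
        h = 0.0
        for k in range(K):
            if k == j:
                continue
            for p in (cm[j, k] / denom, cm[k, j] / denom):
                if p > 0:
                    h -= p * math.log(p, 2 * (K - 1))
        total += w * h
    return total


class TestCEN:
    def test_printed_three_class_example(self):
        cm = np.array([[10, 2, 1], [0, 8, 3], [2, 2, 12]])
        assert cen(cm) == pytest.approx(_cen_bruteforce(cm), abs=1e-12)

    def test_matches_bruteforce_on_random_matrices(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            K = rng.integers(2, 6)
            cm = rng.integers(0, 25, (K, K))
            cm[0, 0] += 1
            assert cen(cm) == pytest.approx(_cen_bruteforce(cm), abs=1e-12)

    def test_class_permutation_invariant(self):
        rng = np.random.default_rng(3)
        cm = rng.integers(0, 20, (4, 4))
        perm = rng.permutation(4)
        assert cen(cm[np.ix_(perm, perm)]) == pytest.approx(cen(cm), abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            cen(np.array([[5]]))


class TestPerClass:
    def test_perfect_classifier_limits(self):
        y = np.repeat([1, 2, 3], 10)
        cm = confusion(y, y, 3)
        scores = np.zeros((30, 3))
        scores[np.arange(30), y - 1] = 1.0
        table = per_class_metrics(cm, scores, y)
        assert np.allclose(table[["Acc", "Sp", "Sn", "MCC", "AUC"]], 1.0)

    def test_never_predicted_class_zero_sensitivity(self):
        y_true = np.array([1, 1, 2, 2, 3, 3])
        y_pred = np.array([1, 1, 2, 2, 1, 2])
        table = per_class_metrics(confusion(y_true, y_pred, 3))
        assert table.loc[3, "Sn"] == 0.0

    def test_binary_collapse_matches_exhaustive_counts(self):
        rng = np.random.default_rng(4)
        y_true = rng.integers(1, 4, 30)
        y_pred = rng.integers(1, 4, 30)
        table = per_class_metrics(confusion(y_true, y_pred, 3))
        for cls in (1, 2, 3):
            tp = int(((y_true == cls) & (y_pred == cls)).sum())
            fn = int(((y_true == cls) & (y_pred != cls)).sum())
            fp = int(((y_true != cls) & (y_pred == cls)).sum())
            tn = int(((y_true != cls) & (y_pred != cls)).sum())
            assert table.loc[cls, "Sn"] == pytest.approx(tp / (tp + fn) if tp + fn else 0)
            assert table.loc[cls, "Sp"] == pytest.approx(tn / (tn + fp) if tn + fp else 0)
            assert table.loc[cls, "Acc"] == pytest.approx((tp + tn) / 30)


class TestAUCAndDeLong:
    def test_midrank_auc_matches_sklearn(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            truth = rng.integers(0, 2, 40).astype(bool)
            if truth.all() or not truth.any():
                continue
            scores = np.round(rng.normal(size=40), 1)  # ties likely
            assert _auc_midrank(scores, truth) == pytest.approx(
                roc_auc_score(truth, scores)
            )

    def test_identical_scores_p_one(self):
        rng = np.random.default_rng(6)
        truth = np.array([True] * 20 + [False] * 20)
        s = rng.normal(size=40)
        auc_a, auc_b, p = delong_test(s, s, truth)
        assert auc_a == auc_b and p == 1.0

    def test_aucs_match_rank_based_estimate(self):
        rng = np.random.default_rng(7)
        truth = rng.integers(0, 2, 50).astype(bool)
        truth[:2] = [True, False]
        a, b = rng.normal(size=50), rng.normal(size=50)
        auc_a, auc_b, _ = delong_test(a, b, truth)
        assert auc_a == pytest.approx(_auc_midrank(a, truth))
        assert auc_b == pytest.approx(_auc_midrank(b, truth))

    def test_p_value_close_to_permutation_oracle(self):
        rng = np.random.default_rng(8)
        truth = np.array([True] * 20 + [False] * 20)
        base = rng.normal(size=40) + truth * 1.2
        a = base + rng.normal(0, 0.4, 40)
        b = base * 0.4 + rng.normal(0, 0.8, 40)
        _, _, p = delong_test(a, b, truth)
        # permutation oracle: swap the paired scores sample-wise
        observed = abs(_auc_midrank(a, truth) - _auc_midrank(b, truth))
        hits = 0
        n_perm = 2000
        for _ in range(n_perm):
            swap = rng.random(40) < 0.5
            ap = np.where(swap, b, a)
            bp = np.where(swap, a, b)
            if abs(_auc_midrank(ap, truth) - _auc_midrank(bp, truth)) >= observed - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        assert p == pytest.approx(p_perm, abs=0.12)

    def test_single_class_truth_errors(self):
        with pytest.raises(ValueError):
            delong_test(np.arange(4.0), np.arange(4.0), np.ones(4, dtype=bool))


class TestImportance:
    def test_sums_to_one_and_planted_scheme_ranks_first(self):
        rng = np.random.default_rng(9)
        n = 200
        signal = rng.normal(size=(n, 3))
        y = (signal.sum(axis=1) > 0).astype(int) + 1
        noise = rng.normal(size=(n, 5))
        X = np.hstack([noise, signal])
        prov = pd.DataFrame(
            {
                "scheme": ["noise"] * 5 + ["planted"] * 3,
                "tag": [f"f{i}" for i in range(8)],
            }
        )
        rf = RandomForestClassifier(100, random_state=0).fit(X, y)
        per_scheme, ranked = aggregate_importance(rf, prov)
        assert per_scheme.sum() == pytest.approx(1.0)
        assert per_scheme.index[0] == "planted"
        assert set(ranked.columns) >= {"scheme", "tag", "importance"}

    def test_provenance_mismatch_rejected(self):
        rf = RandomForestClassifier(10, random_state=0).fit(
            np.random.default_rng(0).normal(size=(20, 4)), [0, 1] * 10
        )
        with pytest.raises(ValueError):
            aggregate_importance(rf, pd.DataFrame({"scheme": ["a"], "tag": ["t"]}))


class TestPipelineFold:
    def test_eval_counts_and_no_synthetic_eval(self, small_corpus):
        ds, struct = small_corpus
        plan = make_split(ds.y, seed=0, n_folds=4)
        opts = PipelineOptions(structure=struct, n_trees=60, seed=0)
        fold = run_pipeline_fold(ds, plan.train_idx, plan.test_idx, opts)
        assert fold.cm.sum() == len(plan.test_idx)
        assert not fold.eval_synthetic.any()
        assert fold.scores.shape == (len(plan.test_idx), ds.class_set.n_classes)

    def test_no_augmentation_matches_manual_run(self, small_corpus):
        from ptmgan.encoders import FeatureEncoder
        from ptmgan.feature_filter import PccFilter

        ds, struct = small_corpus
        plan = make_split(ds.y, seed=1, n_folds=4)
        opts = PipelineOptions(structure=struct, n_trees=60, seed=1)
        fold = run_pipeline_fold(ds, plan.train_idx, plan.test_idx, opts)

        train = [ds.fragments[i] for i in plan.train_idx]
        test = [ds.fragments[i] for i in plan.test_idx]
        enc = FeatureEncoder(structure=struct).fit(train)
        fm_tr, fm_te = enc.transform(train), enc.transform(test)
        filt = PccFilter()
        fm_tr = filt.fit_transform(fm_tr, ds.y[plan.train_idx])
        fm_te = filt.transform(fm_te)
        rf = RandomForestClassifier(60, max_features="sqrt", random_state=1, n_jobs=1)
        rf.fit(fm_tr.X, ds.y[plan.train_idx])
        manual = rf.predict(fm_te.X)
        assert np.array_equal(fold.y_pred, manual)
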