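"""Training, grids, confusion metrics, ROC/AUC, CV and transfer protocols."""

import math

import numpy as np
import pytest

from kcrpred.models import (
    RF_TREE_GRID,
    SVM_C_GRID,
    SVM_GAMMA_GRID,
    EvalReport,
    ModelError,
    ModelSpec,
    confusion_metrics,
    cross_species_eval,
    cross_validate,
    evaluate_scores,
    independent_test,
    roc_auc,
    train,
    undersample_indices,
)


def separable_data(n=60, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(size=(n, 2)) + 6.0 * y[:, None]
    return X, y


class TestGrids:
    def test_svm_grid_is_121_combinations(self):
        spec = ModelSpec("svm_rbf")
        cands = spec.candidates()
        assert len(cands) == 11 * 11 == 121
        assert {c["C"] for c in cands} == {2.0**i for i in range(0, 11)}
        assert {c["gamma"] for c in cands} == {2.0**i for i in range(-10, 1)}

    def test_rf_grid_values(self):
        assert RF_TREE_GRID == (1400, 1600, 1800, 2000, 2200, 2400)
        assert [c["n_estimators"] for c in ModelSpec("random_forest").candidates()] == sorted(RF_TREE_GRID)

    def test_tie_break_order(self):
        cands = ModelSpec("svm_rbf", c_grid=(1.0, 2.0), gamma_grid=(0.5, 1.0)).candidates()
        assert cands[0] == {"C": 1.0, "gamma": 1.0}  # smaller C first, larger gamma first

    def test_unknown_kind_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec("perceptron")


class TestConfusionMetrics:
    def test_symmetric_half(self):
        assert confusion_metrics(25, 25, 25, 25) == (0.5, 0.5, 0.5, 0.0)

    def test_perfect(self):
        assert confusion_metrics(50, 0, 50, 0) == (1.0, 1.0, 1.0, 1.0)

    def test_worked_example(self):
        sn, sp, acc, mcc = confusion_metrics(40, 10, 30, 20)
        assert (sn, sp, acc) == (0.8, 0.6, 0.7)
        assert mcc == pytest.approx(1000 / math.sqrt(6_000_000))
        assert mcc == pytest.approx(0.408, abs=1e-3)

    def test_degenerate_denominator_gives_zero_mcc(self):
        *_, mcc = confusion_metrics(10, 0, 0, 5)
        assert mcc == 0.0

    def test_acc_decomposition_and_bounds_over_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fn, tn, fp = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fn + tn + fp == 0:
                continue
            sn, sp, acc, mcc = confusion_metrics(tp, fn, tn, fp)
            p, n = tp + fn, tn + fp
            if p and n:
                assert acc == pytest.approx((sn * p + sp * n) / (p + n))
            assert -1.0 <= mcc <= 1.0

    def test_mcc_invariant_under_class_swap(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tp, fn, tn, fp = (int(v) for v in rng.integers(1, 50, size=4))
            assert confusion_metrics(tp, fn, tn, fp)[3] == pytest.approx(
                confusion_metrics(tn, fp, tp, fn)[3]
            )

    def test_all_zero_rejected(self):
        with pytest.raises(ModelError):
            confusion_metrics(0, 0, 0, 0)


def concordance_auc(scores, labels):
    """Brute-force pairwise concordance with ties at 1/2."""
    scores = np.asarray(scores)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        auc, _ = roc_auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert auc == 1.0

    def test_all_ties_is_half(self):
        auc, _ = roc_auc([0.5] * 10, [1, 0] * 5)
        assert auc == 0.5

    def test_worked_concordance_example(self):
        auc, _ = roc_auc([0.9, 0.8, 0.7, 0.1], [1, 0, 1, 0])
        assert auc == 0.75

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.normal(size=n), 1)  # coarse -> many ties
            auc, _ = roc_auc(scores, labels)
            assert auc == pytest.approx(concordance_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ModelError):
            roc_auc([0.1, 0.2], [1, 1])


class TestTrain:
    def test_separable_data_reaches_perfect_training_accuracy(self):
        X, y = separable_data()
        model = train(ModelSpec("svm_rbf", c_grid=(1.0,), gamma_grid=(0.1,)), X, y)
        assert np.mean(model.estimator.predict(X) == y) == 1.0

    def test_grid_search_deterministic(self):
        X, y = separable_data(seed=4)
        spec = ModelSpec("svm_rbf", c_grid=(1.0, 4.0), gamma_grid=(0.01, 0.1), seed=9)
        assert train(spec, X, y).params == train(spec, X, y).params

    def test_single_class_rejected(self):
        X, _ = separable_data()
        with pytest.raises(ModelError):
            train(ModelSpec("random_forest", tree_grid=(10,)), X, np.zeros(len(X), dtype=int))


class TestCrossValidate:
    def test_stratified_fold_sizes(self):
        X, y = separable_data(n=200, seed=5)
        report = cross_validate(ModelSpec("random_forest", tree_grid=(30,)), X, y, k=10, seed=1)
        assert report.folds is not None and len(report.folds) == 10
        for fold in report.folds:
            assert fold.tp + fold.fn == 10  # 10 positives per fold
            assert fold.tn + fold.fp == 10

    def test_deterministic_under_seed(self):
        X, y = separable_data(n=100, seed=6)
        spec = ModelSpec("random_forest", tree_grid=(30,), seed=2)
        r1 = cross_validate(spec, X, y, k=5, seed=3)
        r2 = cross_validate(spec, X, y, k=5, seed=3)
        assert r1.to_dict() == r2.to_dict()

    def test_planted_signal_recovers_high_auc(self):
        X, y = separable_data(n=100, seed=7)
        report = cross_validate(ModelSpec("random_forest", tree_grid=(50,)), X, y, k=5, seed=0)
        assert report.auc > 0.95

    def test_class_smaller_than_k_rejected(self):
        X, y = separable_data(n=16)
        with pytest.raises(ModelError):
            cross_validate(ModelSpec("random_forest", tree_grid=(10,)), X, y, k=10, seed=0)


class TestIndependentAndCrossSpecies:
    def test_column_mismatch_named(self):
        X, y = separable_data()
        model = train(
            ModelSpec("random_forest", tree_grid=(20,)), X, y, feature_names=["f0", "f1"]
        )
        with pytest.raises(ModelError, match="f1"):
            independent_test(model, X, y, feature_names=["f0", "g1"])

    def test_empty_test_set_rejected(self):
        X, y = separable_data()
        model = train(ModelSpec("random_forest", tree_grid=(20,)), X, y)
        with pytest.raises(ModelError):
            independent_test(model, np.empty((0, 2)), np.empty(0, dtype=int))

    def test_heldout_auc_close_to_cv_auc(self):
        X, y = separable_data(n=160, seed=8)
        spec = ModelSpec("random_forest", tree_grid=(50,))
        cv_auc = cross_validate(spec, X[:100], y[:100], k=5, seed=0).auc
        model = train(spec, X[:100], y[:100])
        test_auc = independent_test(model, X[100:], y[100:]).auc
        assert abs(cv_auc - test_auc) < 0.1

    def test_undersample_indices_balance(self):
        y = np.array([1] * 10 + [0] * 50)
        idx = undersample_indices(y, seed=4)
        assert np.sum(y[idx] == 1) == np.sum(y[idx] == 0) == 10

    def test_cross_species_identity_case_is_resubstitution(self):
        X, y = separable_data(n=80, seed=9)
        spec = ModelSpec("random_forest", tree_grid=(30,))
        report = cross_species_eval(spec, X, y, X, y, seed=0)
        assert report.extras["cross_species"] is True
        assert report.acc > 0.95  # resubstitution on separable data


def test_permuted_label_null_auc_is_near_half():
    """Over 20 seeds, mean CV AUC under label permutation stays in [0.4, 0.6]."""
    rng = np.random.default_rng(42)
    X = rng.normal(size=(60, 8))
    aucs = []
    for seed in range(20):
        y = np.random.default_rng(seed).permutation([0, 1] * 30)
        spec = ModelSpec("random_forest", tree_grid=(25,), seed=seed)
        aucs.append(cross_validate(spec, X, y, k=10, seed=seed).auc)
    assert 0.4 <= float(np.mean(aucs)) <= 0.6


def test_eval_report_json_roundtrip():
    report = evaluate_scores(np.array([0.9, 0.2, 0.8, 0.1]), np.array([1, 0, 1, 0]), 0.5)
    assert isinstance(report, EvalReport)
    import json

    data = json.loads(report.to_json())
    assert data["tp"] == 2 and data["tn"] == 2
    assert data["auc"] == 1.0
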