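"""Classifier training and evaluation protocols.

Two classifier families are supported, each with a fixed hyperparameter grid
searched by internal stratified 5-fold cross-validation accuracy:

- SVM with RBF kernel: C in {2^0, ..., 2^10}, gamma in {2^-10, ..., 2^0}
  (121 combinations);
- random forest: number of trees in {1400, 1600, 1800, 2000, 2200, 2400}.

Evaluation follows the standard site-predictor protocol: stratified 10-fold
cross-validation, an independent held-out test, and cross-species transfer
(train on species A with undersampling, score the whole of species B).
Metrics are sensitivity, specificity, accuracy, Matthews correlation
coefficient and ROC AUC.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


class ModelError(ValueError):
    """Raised on invalid model specs or degenerate evaluation inputs."""


SVM_C_GRID: tuple[float, ...] = tuple(2.0**i for i in range(0, 11))
SVM_GAMMA_GRID: tuple[float, ...] = tuple(2.0**i for i in range(-10, 1))
RF_TREE_GRID: tuple[int, ...] = (1400, 1600, 1800, 2000, 2200, 2400)


@dataclass
class ModelSpec:
    """Classifier kind plus hyperparameter grid and seed.

    Grids default to the full search space above; override them (e.g. to a
    single point) to skip grid search.
    """

    kind: str  # "svm_rbf" | "random_forest"
    c_grid: tuple[float, ...] = SVM_C_GRID
    gamma_grid: tuple[float, ...] = SVM_GAMMA_GRID
    tree_grid: tuple[int, ...] = RF_TREE_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("svm_rbf", "random_forest"):
            raise ModelError(f"unknown model kind {self.kind!r}")
        self.c_grid = tuple(self.c_grid)
        self.gamma_grid = tuple(self.gamma_grid)
        self.tree_grid = tuple(self.tree_grid)

    def candidates(self) -> list[dict]:
        """Grid points in tie-break order: smaller C first, then larger gamma;
        fewer trees first.  The search keeps the first strict maximum."""
        if self.kind == "svm_rbf":
            return [
                {"C": c, "gamma": g}
                for c in self.c_grid
                for g in sorted(self.gamma_grid, reverse=True)
            ]
        return [{"n_estimators": t} for t in sorted(self.tree_grid)]

    def build(self, params: dict):
        if self.kind == "svm_rbf":
            return SVC(kernel="rbf", C=params["C"], gamma=params["gamma"])
        return RandomForestClassifier(
            n_estimators=params["n_estimators"], random_state=self.seed, n_jobs=1
        )

    @property
    def default_threshold(self) -> float:
        """Decision threshold on scores: 0 for SVM decision values, 0.5 for
        forest positive-class probabilities."""
        return 0.0 if self.kind == "svm_rbf" else 0.5


@dataclass
class TrainedModel:
    estimator: object
    spec: ModelSpec
    params: dict
    cv_accuracy: float | None = None
    feature_names: list[str] | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Decision values (SVM) or positive-class probabilities (forest)."""
        if self.spec.kind == "svm_rbf":
            return self.estimator.decision_function(X)
        return self.estimator.predict_proba(X)[:, 1]


@dataclass
class EvalReport:
    """Confusion counts, derived metrics, ROC, and optional per-fold copies."""

    tp: int
    fn: int
    tn: int
    fp: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    threshold: float = 0.0
    folds: list["EvalReport"] | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roc"] = [[float(a), float(b)] for a, b in self.roc]
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float, float]:
    """(Sn, Sp, Acc, MCC) from confusion counts.

    Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total,
    MCC = (TP*TN - FN*FP) / sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)); MCC is
    defined as 0 when any denominator factor vanishes.
    """
    for v in (tp, fn, tn, fp):
        if v < 0 or int(v) != v:
            raise ModelError("confusion counts must be non-negative integers")
    total = tp + fn + tn + fp
    if total == 0:
        raise ModelError("all confusion counts are zero")
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total
    denom = (tp + fn) * (tn + fp) * (tp + fp) * (tn + fn)
    mcc = (tp * tn - fn * fp) / math.sqrt(denom) if denom else 0.0
    return sn, sp, acc, mcc


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, list[tuple[float, float]]]:
    """ROC by threshold sweep and trapezoid AUC.

    Equals the concordance probability P(score+ > score-) with ties counted
    as 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ModelError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(_trapezoid_auc(fpr, tpr)), list(zip(fpr.tolist(), tpr.tolist()))


def evaluate_scores(
    scores: np.ndarray, labels: np.ndarray, threshold: float, **extras
) -> EvalReport:
    """Build a full report from continuous scores at a decision threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.size == 0:
        raise ModelError("empty evaluation set")
    pred = scores > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    sn, sp, acc, mcc = confusion_metrics(tp, fn, tn, fp)
    if len(np.unique(labels)) == 2:
        auc_val, roc_pts = roc_auc(scores, labels)
    else:
        auc_val, roc_pts = float("nan"), []
    return EvalReport(
        tp=tp, fn=fn, tn=tn, fp=fp, sn=sn, sp=sp, acc=acc, mcc=mcc,
        auc=auc_val, roc=roc_pts, threshold=threshold, extras=dict(extras),
    )


def train(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
    inner_cv: int = 5,
) -> TrainedModel:
    """Grid-search hyperparameters by internal stratified CV accuracy, then
    refit on all training data.

    Single-point grids skip the search.  Ties keep the earlier candidate
    (smaller C, then larger gamma; fewer trees).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ModelError("training labels are single-class")
    candidates = spec.candidates()
    if len(candidates) == 1:
        best, best_acc = candidates[0], None
    else:
        k = min(inner_cv, int(np.min(np.bincount(y))))
        if k < 2:
            raise ModelError("too few samples per class for internal grid-search CV")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=spec.seed)
        folds = list(skf.split(X, y))
        best, best_acc = None, -1.0
        for params in candidates:
            accs = []
            for tr, va in folds:
                est = spec.build(params)
                est.fit(X[tr], y[tr])
                accs.append(np.mean(est.predict(X[va]) == y[va]))
            mean_acc = float(np.mean(accs))
            if mean_acc > best_acc + 1e-12:
                best, best_acc = params, mean_acc
    estimator = spec.build(best)
    estimator.fit(X, y)
    return TrainedModel(
        estimator=estimator,
        spec=spec,
        params=best,
        cv_accuracy=best_acc,
        feature_names=list(feature_names) if feature_names is not None else None,
    )


def cross_validate(
    spec: ModelSpec, X: np.ndarray, y: np.ndarray, k: int = 10, seed: int = 0
) -> EvalReport:
    """Stratified k-fold cross-validation.

    Each fold trains via :func:`train` (including any grid search) on the
    other k-1 folds.  The report pools confusion counts and out-of-fold
    scores across folds (pooled AUC); per-fold reports and the mean of
    per-fold AUCs are attached (``folds``, ``extras['auc_fold_mean']``).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    class_sizes = np.bincount(y, minlength=2)
    if class_sizes.min() < k:
        raise ModelError(f"each class must have >= k={k} samples, got {class_sizes.tolist()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    oof_scores = np.empty(len(y))
    fold_reports: list[EvalReport] = []
    for tr, va in skf.split(X, y):
        model = train(spec, X[tr], y[tr])
        s = model.scores(X[va])
        oof_scores[va] = s
        fold_reports.append(evaluate_scores(s, y[va], spec.default_threshold))
    pooled = evaluate_scores(oof_scores, y, spec.default_threshold)
    pooled.folds = fold_reports
    fold_aucs = [f.auc for f in fold_reports if not math.isnan(f.auc)]
    pooled.extras["auc_fold_mean"] = float(np.mean(fold_aucs)) if fold_aucs else float("nan")
    pooled.extras["k"] = k
    pooled.extras["seed"] = seed
    return pooled


def independent_test(
    model: TrainedModel,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> EvalReport:
    """Single-pass evaluation of a trained model on a held-out set.

    When both the model and the call carry feature names they must match
    exactly (names and order); the first discrepancy is reported.
    """
    if feature_names is not None and model.feature_names is not None:
        for i, (a, b) in enumerate(zip(model.feature_names, feature_names)):
            if a != b:
                raise ModelError(f"feature column {i} mismatch: model {a!r} vs test {b!r}")
        if len(model.feature_names) != len(feature_names):
            raise ModelError(
                f"feature count mismatch: model {len(model.feature_names)} vs test {len(feature_names)}"
            )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if y.size == 0:
        raise ModelError("empty test set")
    return evaluate_scores(model.scores(X), y, model.spec.default_threshold)


def undersample_indices(y: np.ndarray, seed: int) -> np.ndarray:
    """Indices keeping all positives and an equal-size random negative sample."""
    y = np.asarray(y, dtype=int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(neg) <= len(pos):
        return np.arange(len(y))
    rng = random.Random(seed)
    sampled = rng.sample(neg.tolist(), len(pos))
    return np.sort(np.concatenate([pos, np.array(sampled, dtype=int)]))


def cross_species_eval(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> EvalReport:
    """Train on species A (undersampled to balance), test on ALL of species B.

    Mechanics are identical to :func:`independent_test`; the report carries
    ``extras['cross_species'] = True``.
    """
    idx = undersample_indices(np.asarray(y_train, dtype=int), seed)
    model = train(spec, np.asarray(X_train, dtype=float)[idx], np.asarray(y_train, dtype=int)[idx],
                  feature_names=feature_names)
    report = independent_test(model, X_test, y_test, feature_names=feature_names)
    report.extras["cross_species"] = True
    report.extras["chosen_params"] = model.params
    return report
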