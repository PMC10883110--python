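"""Nested cross-validated wrapper selection of the optimal feature subset.

The mRMR-ranked features are added one at a time; for each feature count
x the classifier is evaluated by a stratified outer 5-fold split (4:1)
whose training folds are themselves assessed by an inner stratified
7-fold split (6:1). The feature count x* maximizing the mean inner
validation accuracy (smallest x on ties) defines the optimal feature
subset (OFS); the reported per-fold metrics come from models refit on
each full outer-training fold and scored once on the held-out outer test
fold. Outer-test rows never enter the inner loop, so x* is chosen
without leakage.

Performance is summarized by accuracy, true-positive rate and
true-negative rate,

    ACC = (TP + TN) / (TP + TN + FP + FN),
    TPR = TP / (TP + FN),   TNR = TN / (TN + FP).

The default classifier is a gradient-boosted tree ensemble (LightGBM;
500 iterations, depth 6, learning rate 0.1); a logistic-regression
option keeps quick runs light. The positive class defaults to MCS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .feature_selection import FeatureTable, MrmrRanking

POSITIVE_CLASS = "MCS"


@dataclass
class ClassifierSpec:
    name: str = "gbdt"  # gbdt | logreg
    params: dict[str, Any] = field(default_factory=dict)


@dataclass
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 7
    stratified: bool = True
    unit: str = "window"  # window | subject
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    positive_class: str = POSITIVE_CLASS
    max_features: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("both CV loops need at least 2 folds")
        if self.unit not in ("window", "subject"):
            raise ValueError("unit must be 'window' or 'subject'")


def make_classifier(spec: ClassifierSpec, seed: int):
    if spec.name == "logreg":
        params = {"max_iter": 2000, "C": 1.0}
        params.update(spec.params)
        return LogisticRegression(**params)
    if spec.name == "gbdt":
        from lightgbm import LGBMClassifier

        params = {
            "n_estimators": 500,
            "max_depth": 6,
            "learning_rate": 0.1,
            "n_jobs": 1,
            "verbosity": -1,
            "deterministic": True,
            "force_row_wise": True,
            "min_child_samples": 5,
            "random_state": seed,
        }
        params.update(spec.params)
        return LGBMClassifier(**params)
    raise ValueError(f"unknown classifier '{spec.name}'")


@dataclass
class ClassificationMetrics:
    acc: float
    tpr: float
    tnr: float
    counts: tuple[int, int, int, int]  # (TP, TN, FP, FN)


def compute_metrics(tp: int, tn: int, fp: int, fn: int) -> ClassificationMetrics:
    """Exact accuracy / sensitivity / specificity from confusion counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("at least one prediction required")
    acc = (tp + tn) / total
    tpr = tp / (tp + fn) if tp + fn > 0 else math.nan
    tnr = tn / (tn + fp) if tn + fp > 0 else math.nan
    return ClassificationMetrics(acc=acc, tpr=tpr, tnr=tnr, counts=(tp, tn, fp, fn))


@dataclass
class OfsResult:
    """Accuracy curve, chosen subset size, and per-fold outer metrics."""

    accuracy_curve_mean: np.ndarray  # outer-test accuracy per feature count
    accuracy_curve_sd: np.ndarray
    inner_curve_mean: np.ndarray  # inner-validation accuracy per feature count
    ofs_size: int
    ofs_columns: np.ndarray  # original column indices of the OFS
    fold_metrics: list[ClassificationMetrics]
    fold_indices: list[tuple[np.ndarray, np.ndarray]]  # (train, test) per fold
    positive_class: str
    tfs_size: int | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean([m.acc for m in self.fold_metrics]))


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return tp, tn, fp, fn


def nested_cv_evaluate(
    table: FeatureTable,
    ranking: MrmrRanking,
    cfg: CVConfig | None = None,
    groups: np.ndarray | None = None,
) -> OfsResult:
    """Incremental feature curves under nested stratified cross-validation.

    With ``cfg.unit == "subject"`` pass per-row subject identifiers via
    ``groups``: both CV loops then keep all windows of a subject in the
    same fold, which prevents subject-identity leakage across splits.
    """
    cfg = cfg or CVConfig()
    y = (table.labels == cfg.positive_class).astype(np.int64)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("both classes must be present")
    if min(int(y.sum()), int(y.size - y.sum())) < cfg.outer_folds:
        raise ValueError("each class needs at least outer_folds rows")
    if cfg.unit == "subject" and groups is None:
        raise ValueError("subject-unit CV needs per-row group identifiers")
    grouped = cfg.unit == "subject"
    order = ranking.order
    m = order.size if cfg.max_features is None else min(cfg.max_features, order.size)
    X = table.values[:, order[:m]]

    if grouped:
        outer = StratifiedGroupKFold(cfg.outer_folds, shuffle=True, random_state=cfg.seed)
        outer_splits = list(outer.split(X, y, groups))
    else:
        outer = StratifiedKFold(cfg.outer_folds, shuffle=True, random_state=cfg.seed)
        outer_splits = list(outer.split(X, y))
    outer_acc = np.zeros((cfg.outer_folds, m))
    inner_acc = np.zeros((cfg.outer_folds, m))
    fold_indices: list[tuple[np.ndarray, np.ndarray]] = []
    fold_test_pred: list[np.ndarray] = []  # (m, n_test) predictions per fold

    for f, (tr, te) in enumerate(outer_splits):
        fold_indices.append((tr, te))
        if grouped:
            inner = StratifiedGroupKFold(
                cfg.inner_folds, shuffle=True, random_state=cfg.seed + 1 + f
            )
            inner_splits = list(inner.split(X[tr], y[tr], np.asarray(groups)[tr]))
        else:
            inner = StratifiedKFold(
                cfg.inner_folds, shuffle=True, random_state=cfg.seed + 1 + f
            )
            inner_splits = list(inner.split(X[tr], y[tr]))
        preds = np.zeros((m, te.size), dtype=np.int64)
        for x in range(1, m + 1):
            accs = []
            for itr, iva in inner_splits:
                clf = make_classifier(cfg.classifier, cfg.seed + 17 * f + x)
                clf.fit(X[tr][itr][:, :x], y[tr][itr])
                accs.append(float(np.mean(clf.predict(X[tr][iva][:, :x]) == y[tr][iva])))
            inner_acc[f, x - 1] = float(np.mean(accs))
            clf = make_classifier(cfg.classifier, cfg.seed + 29 * f + x)
            clf.fit(X[tr][:, :x], y[tr])
            preds[x - 1] = clf.predict(X[te][:, :x])
            outer_acc[f, x - 1] = float(np.mean(preds[x - 1] == y[te]))
        fold_test_pred.append(preds)

    inner_mean = inner_acc.mean(axis=0)
    x_star = int(np.argmax(inner_mean)) + 1  # argmax takes the smallest on ties
    fold_metrics = []
    for f, (_tr, te) in enumerate(fold_indices):
        tp, tn, fp, fn = _confusion(y[te], fold_test_pred[f][x_star - 1])
        fold_metrics.append(compute_metrics(tp, tn, fp, fn))
    return OfsResult(
        accuracy_curve_mean=outer_acc.mean(axis=0),
        accuracy_curve_sd=outer_acc.std(axis=0),
        inner_curve_mean=inner_mean,
        ofs_size=x_star,
        ofs_columns=order[:x_star].copy(),
        fold_metrics=fold_metrics,
        fold_indices=fold_indices,
        positive_class=cfg.positive_class,
    )


def summarize_states(per_state_results: dict[str, OfsResult]) -> dict:
    """Per-state mean +/- SD of ACC/TPR/TNR plus the grand mean accuracy."""
    if not per_state_results:
        raise ValueError("at least one state result required")
    report: dict[str, Any] = {"states": {}}
    accs = []
    for state, res in per_state_results.items():
        acc = np.array([m.acc for m in res.fold_metrics])
        tpr = np.array([m.tpr for m in res.fold_metrics])
        tnr = np.array([m.tnr for m in res.fold_metrics])
        report["states"][state] = {
            "accuracy_mean": float(acc.mean()),
            "accuracy_sd": float(acc.std()),
            "sensitivity_mean": float(np.nanmean(tpr)),
            "sensitivity_sd": float(np.nanstd(tpr)),
            "specificity_mean": float(np.nanmean(tnr)),
            "specificity_sd": float(np.nanstd(tnr)),
            "ofs_size": res.ofs_size,
            "tfs_size": res.tfs_size,
            "positive_class": res.positive_class,
        }
        accs.append(acc.mean())
    report["grand_mean_accuracy"] = float(np.mean(accs))
    return report
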