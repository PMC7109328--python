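"""Classifier benchmark: five classifier families, stratified cross-validation,
ACC/SN/SP/MCC and ROC/AUC reporting, and aggregation across balanced splits.

The five families mirror a classic Weka benchmark line-up: random forest,
a C4.5-style entropy decision tree, Gaussian naive Bayes, a linear-kernel
SVM on standardized features, and 1-nearest-neighbour (IBk).  All are
backed by scikit-learn estimators behind a uniform spec interface.

Metric conventions: ACC = (TP+TN)/total, SN = TP/(TP+FN), SP = TN/(TN+FP),
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)).  A metric whose
denominator is zero is reported as 0 and flagged as undefined, so that
aggregation over many splits never aborts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import N_FEATURES, FeatureMatrix

CLASSIFIER_FAMILIES = ("random_forest", "c45_tree", "naive_bayes", "svm", "knn")

#: Default hyperparameters per family.  Random forest: 100 trees and
#: floor(log2(188)) + 1 = 8 candidate features per split; knn: k = 1.
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "random_forest": {
        "n_estimators": 100,
        "max_features": int(math.floor(math.log2(N_FEATURES))) + 1,
    },
    "c45_tree": {"criterion": "entropy", "min_samples_leaf": 2},
    "naive_bayes": {},
    "svm": {"kernel": "linear", "C": 1.0},
    "knn": {"n_neighbors": 1},
}

#: Small documented grids for optional in-CV parameter selection.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "random_forest": {"n_estimators": [50, 100, 200]},
    "c45_tree": {"min_samples_leaf": [1, 2, 5]},
    "naive_bayes": {},
    "svm": {"C": [0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [1, 3, 5]},
}


@dataclass
class ClassifierSpec:
    """A classifier family plus hyperparameters and a seed."""

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in CLASSIFIER_FAMILIES:
            raise ValueError(
                f"unknown classifier family {self.family!r}; "
                f"known: {CLASSIFIER_FAMILIES}"
            )
        merged = dict(DEFAULT_HYPERPARAMETERS[self.family])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def build(self) -> BaseEstimator:
        """Construct the (unfitted) scikit-learn estimator."""
        hp = self.hyperparameters
        if self.family == "random_forest":
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.family == "c45_tree":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.family == "naive_bayes":
            return GaussianNB(**hp)
        if self.family == "svm":
            return Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svm", SVC(random_state=self.seed, **hp)),
                ]
            )
        if self.family == "knn":
            return KNeighborsClassifier(**hp)
        raise AssertionError(self.family)


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of one evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.TP + other.TP,
            self.TN + other.TN,
            self.FP + other.FP,
            self.FN + other.FN,
        )


@dataclass
class Metrics:
    """ACC/SN/SP/MCC with flags naming any zero-denominator metric."""

    acc: float
    sn: float
    sp: float
    mcc: float
    undefined: tuple[str, ...] = ()


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity and Matthews correlation.

    Any metric with a zero denominator is reported as 0 and listed in
    ``undefined`` rather than raising.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    undefined = []
    acc = (tp + tn) / counts.total
    if tp + fn > 0:
        sn = tp / (tp + fn)
    else:
        sn = 0.0
        undefined.append("sn")
    if tn + fp > 0:
        sp = tn / (tn + fp)
    else:
        sp = 0.0
        undefined.append("sp")
    denom = (tp + fn) * (tp + fp) * (tn + fp) * (tn + fn)
    if denom > 0:
        mcc = (tp * tn - fp * fn) / math.sqrt(denom)
    else:
        mcc = 0.0
        undefined.append("mcc")
    return Metrics(acc, sn, sp, mcc, tuple(undefined))


def compute_roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[np.ndarray, float]:
    """ROC curve (rows of fpr, tpr, threshold) and trapezoidal AUC.

    Thresholds sweep the unique scores in descending order with ties grouped
    into single steps; the resulting AUC equals the tie-corrected
    Mann-Whitney statistic.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    curve = np.column_stack([fpr, tpr, thresholds])
    return curve, float(_trapezoid_auc(fpr, tpr))


@dataclass
class EvaluationReport:
    """Confusion counts, summary metrics and ROC/AUC at one aggregation level."""

    classifier: str
    level: str  # "fold" pooled over CV folds, "split" hold-out, "overall"
    counts: ConfusionCounts
    metrics: Metrics
    per_fold: list[ConfusionCounts] = field(default_factory=list)
    roc: Optional[np.ndarray] = None  # columns fpr, tpr, threshold
    auc: Optional[float] = None
    n: int = 0
    seed: Optional[int] = None
    per_report: list[dict] = field(default_factory=list)  # dispersion across splits

    def __post_init__(self) -> None:
        if self.n == 0:
            self.n = self.counts.total

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier,
            "level": self.level,
            "n": self.n,
            "seed": self.seed,
            "counts": vars(self.counts).copy()
            if not isinstance(self.counts, dict)
            else self.counts,
            "acc": self.metrics.acc,
            "sn": self.metrics.sn,
            "sp": self.metrics.sp,
            "mcc": self.metrics.mcc,
            "undefined_metrics": list(self.metrics.undefined),
            "auc": self.auc,
            "per_fold": [
                {"TP": c.TP, "TN": c.TN, "FP": c.FP, "FN": c.FN}
                for c in self.per_fold
            ],
        }
        if self.per_report:
            d["per_report"] = self.per_report
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    def write_roc_tsv(self, path: str | Path) -> None:
        if self.roc is None:
            raise ValueError("report carries no ROC curve")
        header = "fpr\ttpr\tthreshold"
        np.savetxt(path, self.roc, fmt="%.10g", delimiter="\t", header=header, comments="")


def _counts_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return ConfusionCounts(tp, tn, fp, fn)


def _decision_scores(model: BaseEstimator, X: np.ndarray) -> np.ndarray:
    """Continuous scores for the positive class, for ROC construction."""
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def cross_validate(
    matrix: FeatureMatrix,
    spec: ClassifierSpec,
    folds: int = 10,
    seed: int = 0,
    grid: Optional[dict[str, list]] = None,
) -> EvaluationReport:
    """Stratified k-fold cross-validation with pooled confusion counts.

    Out-of-fold decision scores from all folds are pooled into one ROC
    curve.  ``grid`` enables a small in-fold grid search (3-fold inner CV)
    over the given hyperparameter lists.
    """
    y = matrix.y()
    n_minority = int(min(np.sum(y == 1), np.sum(y == 0)))
    if n_minority == 0:
        raise ValueError("cross-validation requires both classes present")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n_minority:
        raise ValueError(
            f"folds ({folds}) exceeds minority-class count ({n_minority})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold: list[ConfusionCounts] = []
    oof_scores = np.empty(len(matrix))
    oof_pred = np.empty(len(matrix), dtype=int)
    for train_idx, test_idx in skf.split(matrix.X, y):
        est = spec.build()
        if grid:
            prefix = "svm__" if spec.family == "svm" else ""
            est = GridSearchCV(
                est,
                {prefix + k: v for k, v in grid.items()},
                cv=3,
                scoring="accuracy",
            )
        est.fit(matrix.X[train_idx], y[train_idx])
        pred = est.predict(matrix.X[test_idx])
        oof_pred[test_idx] = pred
        oof_scores[test_idx] = _decision_scores(est, matrix.X[test_idx])
        per_fold.append(_counts_from_predictions(y[test_idx], pred))
    pooled = sum(per_fold[1:], per_fold[0])
    roc, auc_value = compute_roc_auc(oof_scores, y)
    return EvaluationReport(
        classifier=spec.family,
        level="fold",
        counts=pooled,
        metrics=compute_metrics(pooled),
        per_fold=per_fold,
        roc=roc,
        auc=auc_value,
        n=pooled.total,
        seed=seed,
    )


def fit_classifier(matrix: FeatureMatrix, spec: ClassifierSpec) -> BaseEstimator:
    """Fit the spec's estimator on a full training matrix."""
    est = spec.build()
    est.fit(matrix.X, matrix.y())
    return est


def evaluate_holdout(model: BaseEstimator, test: FeatureMatrix) -> EvaluationReport:
    """Evaluate a fitted model on a held-out matrix.

    With single-class test sets (the negative-only leftovers of the
    undersampling protocol) only accuracy is meaningful — it equals
    specificity — and SN/MCC/AUC are flagged undefined rather than invented.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    n_model_features = getattr(model, "n_features_in_", None)
    if n_model_features is None and hasattr(model, "named_steps"):
        n_model_features = model[0].n_features_in_
    if n_model_features is not None and n_model_features != test.n_features:
        raise ValueError(
            f"model expects {n_model_features} features, matrix has {test.n_features}"
        )
    y = test.y()
    pred = np.asarray(model.predict(test.X), dtype=int)
    counts = _counts_from_predictions(y, pred)
    metrics = compute_metrics(counts)
    roc = auc_value = None
    if len(set(y.tolist())) == 2:
        roc, auc_value = compute_roc_auc(_decision_scores(model, test.X), y)
    return EvaluationReport(
        classifier=type(model).__name__,
        level="split",
        counts=counts,
        metrics=metrics,
        roc=roc,
        auc=auc_value,
        n=counts.total,
    )


def aggregate_reports(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Weighted average of reports across balanced splits.

    Metrics (and AUC where present) are averaged weighted by each report's
    sample count; per-split values are retained for dispersion reporting.
    Confusion counts are summed.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    families = {r.classifier for r in reports}
    if len(families) > 1:
        raise ValueError(f"cannot aggregate across classifier families {families}")
    if len(reports) == 1:
        return reports[0]
    weights = np.array([r.n for r in reports], dtype=float)
    weights /= weights.sum()

    def wmean(values: Sequence[float]) -> float:
        return float(np.dot(weights, np.asarray(values, dtype=float)))

    counts = reports[0].counts
    for r in reports[1:]:
        counts = counts + r.counts
    undefined = tuple(sorted({u for r in reports for u in r.metrics.undefined}))
    metrics = Metrics(
        acc=wmean([r.metrics.acc for r in reports]),
        sn=wmean([r.metrics.sn for r in reports]),
        sp=wmean([r.metrics.sp for r in reports]),
        mcc=wmean([r.metrics.mcc for r in reports]),
        undefined=undefined,
    )
    aucs = [r.auc for r in reports]
    auc_value = wmean([a for a in aucs]) if all(a is not None for a in aucs) else None
    per_report = [
        {"n": r.n, "acc": r.metrics.acc, "sn": r.metrics.sn, "sp": r.metrics.sp,
         "mcc": r.metrics.mcc, "auc": r.auc}
        for r in reports
    ]
    return EvaluationReport(
        classifier=reports[0].classifier,
        level="overall",
        counts=counts,
        metrics=metrics,
        auc=auc_value,
        n=int(sum(r.n for r in reports)),
        per_report=per_report,
    )
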