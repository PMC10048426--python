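"""Variety classification bench: eight models, stratified k-fold CV,
feature-importance selection, grid search, metrics and one-vs-rest ROC.

Estimators are scikit-learn's (the natural choice for tabular grain
features); everything that defines the evaluation protocol — the confusion
matrix bookkeeping, precision/recall/F1 identities, the macro averages, the
ROC threshold sweep and trapezoidal AUC — is computed here explicitly so the
report invariants (row sums = supports, accuracy = trace/total, F1 =
harmonic mean) hold by construction and can be cross-checked against
scikit-learn in the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .errors import (
    DegenerateTrainingError,
    InvalidInputError,
    StratificationError,
    UnsupportedModelError,
)

__all__ = [
    "MODEL_KINDS",
    "ClassifierSpec",
    "CVPlan",
    "EvalReport",
    "RocCurve",
    "ImportanceRanking",
    "make_estimator",
    "harmonic_f1",
    "stratified_kfold",
    "train",
    "evaluate",
    "cross_validate",
    "rank_and_select_features",
    "grid_search",
    "roc_one_vs_rest",
]

MODEL_KINDS = (
    "lr",
    "dt",
    "rf",
    "mlp",
    "svm-linear",
    "svm-poly",
    "svm-rbf",
    "svm-sigmoid",
)

_SCALED = {"lr", "mlp", "svm-linear", "svm-poly", "svm-rbf", "svm-sigmoid"}


@dataclass(frozen=True)
class ClassifierSpec:
    """One bench entry: model kind + hyperparameters + seed."""

    model_kind: str
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model_kind not in MODEL_KINDS:
            raise InvalidInputError(
                f"unknown model kind {self.model_kind!r}; valid: {MODEL_KINDS}"
            )


@dataclass(frozen=True)
class CVPlan:
    """Stratified k-fold plan (stratification is not optional)."""

    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise InvalidInputError("k must be >= 2")


def make_estimator(spec: ClassifierSpec):
    """Instantiate the scikit-learn estimator for a spec.

    Scale-sensitive models (LR, MLP, all SVM kernels) are wrapped in a
    standardization pipeline; tree models consume raw features.  All SVMs
    fit Platt-scaled probabilities so every bench member exposes
    per-class scores for ROC analysis.
    """
    p = dict(spec.params)
    seed = spec.seed
    kind = spec.model_kind
    if kind == "lr":
        est = LogisticRegression(max_iter=int(p.pop("max_iter", 3000)), **p)
    elif kind == "dt":
        est = DecisionTreeClassifier(random_state=seed, **p)
    elif kind == "rf":
        est = RandomForestClassifier(
            n_estimators=int(p.pop("n_trees", 200)),
            max_depth=p.pop("max_depth", None),
            min_samples_split=int(p.pop("min_samples_split", 2)),
            min_samples_leaf=int(p.pop("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
            **p,
        )
    elif kind == "mlp":
        est = MLPClassifier(
            hidden_layer_sizes=p.pop("hidden_layer_sizes", (64,)),
            max_iter=int(p.pop("max_iter", 600)),
            random_state=seed,
            **p,
        )
    else:
        kernel = kind.split("-", 1)[1]
        kernel = {"poly": "poly", "linear": "linear", "rbf": "rbf", "sigmoid": "sigmoid"}[kernel]
        est = SVC(kernel=kernel, probability=True, random_state=seed, **p)
    if kind in _SCALED:
        return Pipeline([("scale", StandardScaler()), ("model", est)])
    return est


def stratified_kfold(
    y: Sequence, plan: CVPlan
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic stratified folds as (train_idx, test_idx) pairs.

    Raises :class:`StratificationError` naming the first class with fewer
    than k samples.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    for cls, cnt in zip(classes, counts):
        if cnt < plan.k:
            raise StratificationError(
                f"class {cls!r} has {cnt} samples, fewer than k={plan.k}"
            )
    skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def train(spec: ClassifierSpec, X: np.ndarray, y: Sequence):
    """Fit the estimator for ``spec``; rejects single-class training sets."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not np.isfinite(X).all():
        raise InvalidInputError("features must be finite")
    if np.unique(y).size < 2:
        raise DegenerateTrainingError("training set contains a single class")
    model = make_estimator(spec)
    model.fit(X, y)
    return model


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 score: harmonic mean of precision and recall (0 when both are 0)."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


@dataclass
class EvalReport:
    """Confusion matrix plus the derived per-class and macro metrics.

    ``per_class[c]`` holds precision, recall, f1 and support for class c;
    macro metrics are unweighted class means, weighted metrics are
    support-weighted.
    """

    labels: list
    confusion: np.ndarray
    per_class: dict
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_f1: float
    folds: list["EvalReport"] = field(default_factory=list)

    @classmethod
    def from_confusion(cls, confusion: np.ndarray, labels: Sequence) -> "EvalReport":
        confusion = np.asarray(confusion, int)
        total = confusion.sum()
        if total == 0:
            raise InvalidInputError("empty confusion matrix")
        per_class = {}
        for idx, lab in enumerate(labels):
            tp = confusion[idx, idx]
            fp = confusion[:, idx].sum() - tp
            fn = confusion[idx, :].sum() - tp
            precision = tp / (tp + fp) if tp + fp > 0 else 0.0
            recall = tp / (tp + fn) if tp + fn > 0 else 0.0
            f1 = harmonic_f1(precision, recall)
            per_class[lab] = {
                "precision": float(precision),
                "recall": float(recall),
                "f1": float(f1),
                "support": int(confusion[idx, :].sum()),
            }
        supports = np.array([per_class[lab]["support"] for lab in labels], float)
        f1s = np.array([per_class[lab]["f1"] for lab in labels])
        return cls(
            labels=list(labels),
            confusion=confusion,
            per_class=per_class,
            accuracy=float(np.trace(confusion) / total),
            macro_precision=float(
                np.mean([per_class[lab]["precision"] for lab in labels])
            ),
            macro_recall=float(np.mean([per_class[lab]["recall"] for lab in labels])),
            macro_f1=float(np.mean(f1s)),
            weighted_f1=float((f1s * supports).sum() / supports.sum()),
        )

    def to_json(self) -> dict:
        return {
            "labels": [str(lab) for lab in self.labels],
            "confusion": self.confusion.tolist(),
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "weighted_f1": self.weighted_f1,
            "fold_accuracies": [f.accuracy for f in self.folds],
            "fold_macro_f1": [f.macro_f1 for f in self.folds],
        }


def confusion_matrix(
    y_true: Sequence, y_pred: Sequence, labels: Sequence
) -> np.ndarray:
    """Rows = actual class, columns = predicted class."""
    index = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros((len(labels), len(labels)), int)
    for t, p in zip(y_true, y_pred):
        out[index[t], index[p]] += 1
    return out


def evaluate(model, X: np.ndarray, y: Sequence, labels: Sequence | None = None) -> EvalReport:
    """Score a fitted model on a test split."""
    y = np.asarray(y)
    if len(y) == 0:
        raise InvalidInputError("empty test set")
    if labels is None:
        labels = list(model.classes_)
    unknown = set(y) - set(labels)
    if unknown:
        raise InvalidInputError(f"test labels outside the training set: {unknown}")
    pred = model.predict(np.asarray(X, float))
    return EvalReport.from_confusion(confusion_matrix(y, pred, labels), labels)


def cross_validate(
    X: np.ndarray, y: Sequence, spec: ClassifierSpec, plan: CVPlan
) -> EvalReport:
    """Stratified k-fold CV; the aggregate report pools the fold confusion
    matrices and keeps per-fold reports (mean/min/max derivable)."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    labels = list(np.unique(y))
    folds = []
    pooled = np.zeros((len(labels), len(labels)), int)
    for tr, te in stratified_kfold(y, plan):
        model = train(spec, X[tr], y[tr])
        rep = evaluate(model, X[te], y[te], labels=labels)
        folds.append(rep)
        pooled += rep.confusion
    agg = EvalReport.from_confusion(pooled, labels)
    agg.folds = folds
    return agg


def mean_fold_accuracy(report: EvalReport) -> float:
    return float(np.mean([f.accuracy for f in report.folds]))


@dataclass
class ImportanceRanking:
    """Normalized feature importances with the selected top block."""

    names: list[str]
    importances: np.ndarray
    selected: list[str]


def rank_and_select_features(
    model,
    feature_names: Sequence[str],
    *,
    top_n: int | None = 59,
    threshold: float | None = None,
) -> ImportanceRanking:
    """Rank features by a fitted tree model's impurity importances.

    Defaults to keeping the top 59 features; ``threshold`` mode keeps every
    feature whose normalized importance exceeds it.  Ties and order are
    resolved by descending importance then original column order.
    """
    est = model.named_steps["model"] if isinstance(model, Pipeline) else model
    if not hasattr(est, "feature_importances_"):
        raise UnsupportedModelError(
            "feature ranking requires a tree-based model with feature_importances_"
        )
    imp = np.asarray(est.feature_importances_, float)
    if imp.sum() > 0:
        imp = imp / imp.sum()
    order = np.lexsort((np.arange(len(imp)), -imp))
    if threshold is not None:
        selected = [feature_names[i] for i in order if imp[i] > threshold]
    else:
        n = min(int(top_n), len(imp))
        selected = [feature_names[i] for i in order[:n]]
    return ImportanceRanking(list(feature_names), imp, selected)


def grid_search(
    X: np.ndarray,
    y: Sequence,
    model_kind: str,
    grid: Mapping[str, Sequence],
    plan: CVPlan,
    *,
    seed: int = 0,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Exhaustive Cartesian grid search scored by CV mean macro-F1.

    Ties break to the first combination in deterministic grid order.
    """
    if not grid:
        raise InvalidInputError("empty hyperparameter grid")
    axes = list(grid.items())
    records = []
    best_spec = None
    best_score = -np.inf
    for combo in itertools.product(*(vals for _, vals in axes)):
        params = {name: val for (name, _), val in zip(axes, combo)}
        spec = ClassifierSpec(model_kind, params, seed=seed)
        report = cross_validate(X, y, spec, plan)
        score = float(np.mean([f.macro_f1 for f in report.folds]))
        records.append({**params, "cv_macro_f1": score,
                        "cv_accuracy": mean_fold_accuracy(report)})
        if score > best_score:
            best_score = score
            best_spec = spec
    return best_spec, pd.DataFrame(records)


@dataclass
class RocCurve:
    """One-vs-rest ROC for a single class."""

    label: object
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float | None
    defined: bool = True


def _binary_roc(scores: np.ndarray, positive: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold sweep over sorted unique scores (plus sentinels)."""
    thresholds = np.concatenate(
        [[np.inf], np.unique(scores)[::-1], [-np.inf]]
    )
    n_pos = int(positive.sum())
    n_neg = int(len(positive) - n_pos)
    tpr = np.empty(len(thresholds))
    fpr = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        pred = scores >= t
        tpr[i] = (pred & positive).sum() / n_pos
        fpr[i] = (pred & ~positive).sum() / n_neg
    return fpr, tpr, thresholds


def roc_one_vs_rest(model, X: np.ndarray, y: Sequence) -> dict[object, RocCurve]:
    """Per-class ROC curves from the model's class-membership scores.

    A class absent from the test set yields an undefined curve (flagged),
    not an exception.  AUC is the trapezoidal area under the sweep.
    """
    y = np.asarray(y)
    scores = model.predict_proba(np.asarray(X, float))
    curves: dict[object, RocCurve] = {}
    for idx, lab in enumerate(model.classes_):
        positive = y == lab
        if positive.all() or not positive.any():
            curves[lab] = RocCurve(
                lab, np.array([]), np.array([]), np.array([]), None, defined=False
            )
            continue
        fpr, tpr, thr = _binary_roc(scores[:, idx], positive)
        auc = float(np.trapezoid(tpr, fpr))
        curves[lab] = RocCurve(lab, fpr, tpr, thr, auc)
    return curves
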