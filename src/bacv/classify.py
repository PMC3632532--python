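"""Linear-SVM classification of homodimers vs crystal packing from ACVs.

The classifier is a soft-margin linear SVM trained on min-max-scaled
contact-vector features, with recursive feature elimination (SVM-RFE):
features are ranked by squared weight, the weakest is removed one per step,
and stratified 5-fold cross-validation accuracy is recorded at every subset
size; the subset maximizing CV accuracy is selected (ties broken toward
fewer features).  Evaluation uses leave-one-out cross-validation on a
learning set or a frozen model applied to an independent set, scored by
recall, specificity, accuracy and Matthews correlation coefficient.  The
positive class (+1) is the biological homodimer, so recall is the fraction
of true dimers recovered.

A shallow decision tree on the RFE-selected features provides interpretable
integer-threshold rules of the form ``<type pair> [bin] > t: class``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .acv_features import LabeledDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class EvalMetrics:
    """Confusion counts and the four derived scores."""

    tp: int
    fp: int
    tn: int
    fn: int
    recall: float
    specificity: float
    accuracy: float
    mcc: float
    mcc_undefined: bool = False

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "recall": self.recall, "specificity": self.specificity,
            "accuracy": self.accuracy, "mcc": self.mcc,
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> EvalMetrics:
    """Recall, specificity, accuracy and MCC from a 2x2 confusion matrix.

    Recall (or specificity) is NaN when the positive (or negative) class is
    empty.  When the MCC denominator vanishes the MCC is reported as 0 with
    ``mcc_undefined`` set.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    n = tp + fp + tn + fn
    if n == 0:
        raise ValueError("empty confusion matrix")
    if tp + fn == 0:
        logger.warning("no positive samples: recall undefined")
        recall = float("nan")
    else:
        recall = tp / (tp + fn)
    if tn + fp == 0:
        logger.warning("no negative samples: specificity undefined")
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    accuracy = (tp + tn) / n
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        return EvalMetrics(tp, fp, tn, fn, recall, specificity, accuracy, 0.0, True)
    mcc = (tp * tn - fp * fn) / denom
    return EvalMetrics(tp, fp, tn, fn, recall, specificity, accuracy, mcc)


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> EvalMetrics:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))
    return compute_metrics(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# model


@dataclass
class ClassifierModel:
    """A trained linear SVM: weights, bias and frozen min-max scaling."""

    selected_features: tuple[str, ...]
    weights: np.ndarray  # per selected feature, on the scaled axes
    bias: float
    scale_min: np.ndarray
    scale_range: np.ndarray  # 0 entries mark constant training columns
    C: float = 1.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.scale_min = np.asarray(self.scale_min, dtype=float)
        self.scale_range = np.asarray(self.scale_range, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite SVM weights")

    def _scale(self, X: np.ndarray) -> np.ndarray:
        rng = np.where(self.scale_range == 0, 1.0, self.scale_range)
        return (X - self.scale_min) / rng

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self._scale(X) @ self.weights + self.bias

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(X) >= 0, 1, -1)

    def predict(self, data: LabeledDataset) -> np.ndarray:
        missing = [f for f in self.selected_features if f not in data.labels]
        if missing:
            raise ValueError(f"test data lacks model features: {missing[:5]}...")
        return self.predict_matrix(data.subset(self.selected_features).X)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "selected_features": list(self.selected_features),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "scale_min": self.scale_min.tolist(),
            "scale_range": self.scale_range.tolist(),
            "C": self.C,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(payload["selected_features"]),
            np.array(payload["weights"]),
            float(payload["bias"]),
            np.array(payload["scale_min"]),
            np.array(payload["scale_range"]),
            float(payload["C"]),
            payload.get("metadata", {}),
        )


def train_svm(
    data: LabeledDataset,
    features: Sequence[str] | None = None,
    C: float = 1.0,
) -> ClassifierModel:
    """Fit a linear soft-margin SVM on a feature subset.

    Features are min-max scaled to [0, 1] using the training rows only;
    the scaling is frozen into the model so independent-set prediction
    reuses it.  Deterministic given the data and C.
    """
    features = tuple(features) if features is not None else data.labels
    if not features:
        raise ValueError("empty feature subset")
    sub = data.subset(features)
    X = sub.X.astype(float)
    y = sub.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    if np.all(rng == 0):
        raise ValueError("all features are constant on the training data")
    Xs = (X - lo) / np.where(rng == 0, 1.0, rng)
    svc = SVC(kernel="linear", C=C)
    svc.fit(Xs, y)
    # sklearn orders classes [-1, +1], so coef_ already points toward +1
    return ClassifierModel(
        selected_features=features,
        weights=svc.coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        scale_min=lo,
        scale_range=rng,
        C=C,
        metadata={"n_train": len(y), "variant": data.variant, "definition": data.definition},
    )


# ---------------------------------------------------------------------------
# SVM-RFE


@dataclass
class RFEResult:
    """Selected subset plus the CV-accuracy trace of the elimination path."""

    selected_features: tuple[str, ...]
    trace: list[tuple[int, float]]  # (subset size, CV accuracy), size descending
    elimination_order: list[str]  # first removed first
    seed: int = 0


def _cv_accuracy(
    data: LabeledDataset, features: Sequence[str], C: float, cv_folds: int, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    sub = data.subset(features)
    correct = 0
    for train_idx, test_idx in skf.split(sub.X, sub.y):
        fold_train = LabeledDataset(
            sub.X[train_idx], sub.y[train_idx],
            [sub.ids[i] for i in train_idx], sub.labels, sub.variant, sub.definition,
        )
        model = train_svm(fold_train, C=C)
        pred = model.predict_matrix(sub.X[test_idx])
        correct += int(np.sum(pred == sub.y[test_idx]))
    return correct / len(sub.y)


def rfe_select(
    data: LabeledDataset,
    C: float = 1.0,
    cv_folds: int = 5,
    seed: int = 0,
) -> RFEResult:
    """SVM-RFE: drop the smallest-|w| feature per step, track CV accuracy.

    At every subset size a stratified ``cv_folds``-fold cross-validation
    accuracy is recorded; the returned subset is the one with maximal CV
    accuracy, ties resolved toward fewer features.  The trace has one entry
    per initial feature (sizes n, n-1, ..., 1).
    """
    features = list(data.labels)
    trace: list[tuple[int, float]] = []
    eliminated: list[str] = []
    best_subset: tuple[str, ...] = tuple(features)
    best_acc = -1.0
    while features:
        acc = _cv_accuracy(data, features, C, cv_folds, seed)
        trace.append((len(features), acc))
        if acc >= best_acc:  # >= prefers the later (smaller) subset on ties
            best_acc = acc
            best_subset = tuple(features)
        if len(features) == 1:
            break
        model = train_svm(data, features, C=C)
        weakest = int(np.argmin(model.weights**2))
        eliminated.append(features.pop(weakest))
    return RFEResult(best_subset, trace, eliminated, seed)


# ---------------------------------------------------------------------------
# evaluation protocols


def evaluate_loocv(
    data: LabeledDataset,
    features: Sequence[str] | None = None,
    C: float = 1.0,
) -> EvalMetrics:
    """Leave-one-out cross-validation: n train/predict rounds, pooled metrics."""
    n = len(data)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    features = tuple(features) if features is not None else data.labels
    sub = data.subset(features)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train = LabeledDataset(
            sub.X[mask], sub.y[mask],
            [sub.ids[j] for j in range(n) if j != i],
            sub.labels, sub.variant, sub.definition,
        )
        model = train_svm(train, C=C)
        preds[i] = model.predict_matrix(sub.X[i : i + 1])[0]
    return metrics_from_predictions(sub.y, preds)


def evaluate_independent(model: ClassifierModel, test_data: LabeledDataset) -> EvalMetrics:
    """Apply a frozen model (weights and scaling) to unseen interfaces."""
    preds = model.predict(test_data)
    return metrics_from_predictions(test_data.y, preds)


# ---------------------------------------------------------------------------
# decision-tree rule extraction


@dataclass
class DecisionTreeResult:
    tree: DecisionTreeClassifier
    features: tuple[str, ...]
    cv_accuracy: float
    rules: str


def _format_rules(tree: DecisionTreeClassifier, features: Sequence[str]) -> str:
    """Serialize branches as indented integer-threshold rules.

    Each line reads ``<feature> > t`` or ``<feature> <= t`` followed, at a
    leaf, by the class label (``Dimers`` for +1, ``CP`` for -1) and
    ``(n/m)``: samples reaching the leaf / misclassified among them.
    """
    t = tree.tree_
    class_names = {0: "CP", 1: "Dimers"}  # sklearn class order is [-1, +1]
    lines: list[str] = []

    def leaf_suffix(node: int) -> str:
        counts = t.value[node][0] * t.weighted_n_node_samples[node]
        counts = np.rint(counts).astype(int)
        winner = int(np.argmax(counts))
        n_here = int(counts.sum())
        mis = n_here - int(counts[winner])
        return f": {class_names[winner]} ({n_here}/{mis})"

    def walk(node: int, depth: int) -> None:
        indent = "|   " * depth
        if t.children_left[node] == -1:
            lines.append(f"{indent}{leaf_suffix(node).lstrip(': ')}")
            return
        feat = features[t.feature[node]]
        thr = int(math.floor(t.threshold[node]))  # counts are integers: x.5 -> x
        for op, child in (("<=", t.children_left[node]), (">", t.children_right[node])):
            suffix = leaf_suffix(child) if t.children_left[child] == -1 else ""
            lines.append(f"{indent}{feat} {op} {thr}{suffix}")
            if not suffix:
                walk(child, depth + 1)

    walk(0, 0)
    return "\n".join(lines)


def fit_decision_tree(
    data: LabeledDataset,
    features: Sequence[str] | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> DecisionTreeResult:
    """Entropy-split decision tree on (typically RFE-selected) count features.

    Thresholds are effectively integer because the inputs are occurrence
    counts; minimum leaf size is 2.  Reports stratified ``cv_folds``-fold CV
    accuracy alongside the serialized rules.
    """
    features = tuple(features) if features is not None else data.labels
    sub = data.subset(features)
    clf_args = dict(criterion="entropy", min_samples_leaf=2, random_state=seed)
    n_classes = len(np.unique(sub.y))
    if n_classes > 1:
        skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        correct = 0
        for train_idx, test_idx in skf.split(sub.X, sub.y):
            fold = DecisionTreeClassifier(**clf_args)
            fold.fit(sub.X[train_idx], sub.y[train_idx])
            correct += int(np.sum(fold.predict(sub.X[test_idx]) == sub.y[test_idx]))
        cv_acc = correct / len(sub.y)
    else:
        cv_acc = 1.0
    tree = DecisionTreeClassifier(**clf_args)
    tree.fit(sub.X, sub.y)
    return DecisionTreeResult(tree, features, cv_acc, _format_rules(tree, features))
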