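"""Linear SVM training and k-fold evaluation for murmur diagnosis.

Labels follow the y = +1 (healthy) / -1 (pathological) coding.  The
classifier is the soft-margin linear SVM minimizing |w|^2/2 plus slack;
hard margin is recovered as the regularization parameter grows.  Features
are z-standardized with parameters fit on the training data only, and the
scaling is stored in the model so prediction is self-contained.

Evaluation uses stratified k-fold cross-validation (default k=8) with a
seeded shuffle; every recording is predicted exactly once out-of-fold, and
the pooled out-of-fold decision values give the ROC curve and AUC.  The
ROC treats +1 as the positive class and handles tied decision values by
grouping thresholds, which makes the trapezoidal area equal to the
pairwise concordance probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .errors import ParameterError, TrainingError, ValidationError


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix (recordings x features) and +-1 labels."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.features, dtype=np.float64)
        y = np.asarray(self.labels, dtype=np.int64)
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y)
        if x.ndim != 2:
            raise ValidationError("features must be a 2-D matrix")
        if y.shape != (x.shape[0],):
            raise ValidationError("labels must match the number of feature rows")
        if not np.all(np.isin(y, (-1, 1))):
            raise ValidationError("labels must be +1 or -1")
        if not np.all(np.isfinite(x)):
            raise ValidationError("features must be finite")


@dataclass(frozen=True)
class TrainedModel:
    """Linear decision rule sign(w.x - b) with its feature standardization."""

    w: np.ndarray
    b: float
    center: np.ndarray
    scale: np.ndarray

    @property
    def margin(self) -> float:
        return 2.0 / float(np.linalg.norm(self.w))


@dataclass(frozen=True)
class EvalReport:
    confusion: np.ndarray  # rows actual, cols predicted; order (normal, pathological)
    accuracy: float  # percent
    per_class_percent_correct: tuple[float, float]
    roc_points: np.ndarray  # (fpr, tpr) rows
    auc: float
    fold_assignments: np.ndarray

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy_pct": self.accuracy,
            "per_class_percent_correct": list(self.per_class_percent_correct),
            "roc_points": self.roc_points.tolist(),
            "auc": self.auc,
            "fold_assignments": self.fold_assignments.tolist(),
        }


def train_linear_svm(
    data: LabeledDataset, regularization: float = 1.0, standardize: bool = True
) -> TrainedModel:
    """Fit the soft-margin linear SVM; ``regularization`` is the slack
    penalty (hard margin as it grows large)."""
    if regularization <= 0:
        raise ParameterError("regularization must be positive")
    y = data.labels
    if np.unique(y).size < 2:
        raise TrainingError("training data contains a single class")
    x = data.features
    if standardize:
        center = x.mean(axis=0)
        scale = x.std(axis=0)
        scale = np.where(scale > 0, scale, 1.0)
    else:
        center = np.zeros(x.shape[1])
        scale = np.ones(x.shape[1])
    xs = (x - center) / scale
    svc = SVC(kernel="linear", C=regularization)
    svc.fit(xs, y)
    w = svc.coef_.ravel().copy()
    b = -float(svc.intercept_[0])  # decision rule is w.x - b
    return TrainedModel(w=w, b=b, center=center, scale=scale)


def predict(model: TrainedModel, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (tie at the boundary -> +1, healthy) and decision values w.x - b."""
    x = np.atleast_2d(np.asarray(features, dtype=np.float64))
    if x.shape[1] != model.w.size:
        raise ParameterError(
            f"feature dimension {x.shape[1]} does not match model ({model.w.size})"
        )
    xs = (x - model.center) / model.scale
    decision = xs @ model.w - model.b
    labels = np.where(decision >= 0, 1, -1)
    return labels, decision


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment with near-equal fold sizes.

    Each class is shuffled and dealt round-robin over the k folds; the
    second class starts k//2 folds later so the overall fold sizes differ
    by at most one (e.g. 58+58 with k=8 gives four folds of 15 and four
    of 14, each holding 7-8 recordings per class).
    """
    y = np.asarray(labels)
    if k < 2:
        raise ParameterError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(y.size, -1, dtype=np.int64)
    for offset_mult, cls in enumerate(sorted(np.unique(y).tolist())):
        idx = np.nonzero(y == cls)[0]
        if idx.size < k:
            raise ParameterError(f"class {cls} has fewer members than k={k}")
        rng.shuffle(idx)
        start = offset_mult * (k // 2)
        folds[idx] = (np.arange(idx.size) + start) % k
    return folds


def confusion_metrics(confusion: np.ndarray) -> tuple[float, tuple[float, ...]]:
    """Overall accuracy and per-class percent correct, to one decimal.

    Rows are actual classes, columns predicted; accuracy is
    100 * trace / total and each per-class percent is 100 * diagonal /
    row sum.
    """
    c = np.asarray(confusion, dtype=np.float64)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ParameterError("confusion matrix must be square")
    if np.any(c < 0):
        raise ParameterError("confusion counts must be nonnegative")
    total = c.sum()
    if total == 0:
        raise ParameterError("confusion matrix is empty")
    accuracy = round(100.0 * np.trace(c) / total, 1)
    row_sums = c.sum(axis=1)
    per_class = tuple(
        round(100.0 * c[i, i] / row_sums[i], 1) if row_sums[i] > 0 else 0.0
        for i in range(c.shape[0])
    )
    return accuracy, per_class


def roc_auc(decision_values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC curve and AUC with +1 as the positive class.

    Thresholds sweep the sorted unique decision values; tied values move
    along a single ROC segment, so the trapezoidal AUC equals the
    concordance probability (ties counted half).
    """
    scores = np.asarray(decision_values, dtype=np.float64)
    y = np.asarray(labels)
    pos = y == 1
    neg = y == -1
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tp = np.cumsum(pos[order])
    fp = np.cumsum(neg[order])
    # keep only the last index of each tied-score group
    distinct = np.nonzero(np.diff(sorted_scores, append=-np.inf) != 0)[0]
    tpr = np.concatenate([[0.0], tp[distinct] / n_pos])
    fpr = np.concatenate([[0.0], fp[distinct] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def kfold_cross_validate(
    data: LabeledDataset,
    k: int = 8,
    seed: int = 0,
    regularization: float = 1.0,
) -> EvalReport:
    """Stratified k-fold evaluation with pooled out-of-fold decisions.

    Standardization and the SVM are fit on each training split only; the
    held-out fold is predicted once.  The confusion matrix rows/columns
    are ordered (normal = +1, pathological = -1).
    """
    y = data.labels
    folds = stratified_folds(y, k, seed)
    predictions = np.zeros(y.size, dtype=np.int64)
    decisions = np.zeros(y.size)
    for f in range(k):
        test = folds == f
        train = ~test
        model = train_linear_svm(
            LabeledDataset(data.features[train], y[train]), regularization
        )
        predictions[test], decisions[test] = predict(model, data.features[test])
    confusion = np.zeros((2, 2), dtype=np.int64)
    class_order = (1, -1)  # (normal, pathological)
    for i, actual in enumerate(class_order):
        for j, predicted in enumerate(class_order):
            confusion[i, j] = int(np.sum((y == actual) & (predictions == predicted)))
    accuracy, per_class = confusion_metrics(confusion)
    roc_points, auc = roc_auc(decisions, y)
    return EvalReport(
        confusion=confusion,
        accuracy=accuracy,
        per_class_percent_correct=per_class,
        roc_points=roc_points,
        auc=auc,
        fold_assignments=folds,
    )
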