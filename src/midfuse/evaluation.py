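"""Model evaluation: leave-one-out cross-validation, confusion matrices,
sensitivity / specificity / precision / accuracy, ROC curves and Welch
t-tests for explaining group differences in sensor responses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .data_model import DataError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Integer count matrix; rows are true classes, columns predicted."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        g = len(self.classes)
        if counts.shape != (g, g):
            raise DataError(f"counts must be {g}x{g}")
        if (counts < 0).any():
            raise DataError("negative count")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes),
                            columns=list(self.classes))


def confusion(true, pred, class_order: Sequence[str] | None = None) -> ConfusionMatrix:
    """Build a confusion matrix; class order defaults to first appearance in ``true``."""
    true, pred = list(true), list(pred)
    if len(true) != len(pred):
        raise DataError("true and pred must have equal length")
    if class_order is None:
        class_order = []
        for t in true:
            if t not in class_order:
                class_order.append(t)
    classes = tuple(class_order)
    index = {c: k for k, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, pred):
        if t not in index:
            raise DataError(f"true label {t!r} not in class order")
        if p not in index:
            raise DataError(f"predicted label {p!r} not in class order")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy plus (macro-averaged for multi-class) Se / Sp / Pre."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    per_class: pd.DataFrame
    positive_class: str | None = None

    def as_dict(self) -> dict[str, float]:
        return {
            "Ac": self.accuracy,
            "Se": self.sensitivity,
            "Sp": self.specificity,
            "Pre": self.precision,
        }


def metrics(cm: ConfusionMatrix, positive_class: str | None = None) -> MetricsReport:
    """Compute Ac / Se / Sp / Pre from a confusion matrix.

    Binary with a declared positive class: Se is the positive-class
    recall, Sp the negative-class recall, Pre the positive predictive
    value. Otherwise one-vs-rest values are macro-averaged over classes
    with defined denominators (empty classes are skipped with a
    warning).
    """
    counts = cm.counts
    total = cm.total
    if total == 0:
        raise DataError("empty confusion matrix")
    acc = float(np.trace(counts)) / total

    rows: list[dict] = []
    for k, c in enumerate(cm.classes):
        tp = counts[k, k]
        fn = counts[k].sum() - tp
        fp = counts[:, k].sum() - tp
        tn = total - tp - fn - fp
        rows.append({
            "class": c,
            "recall": tp / (tp + fn) if tp + fn > 0 else np.nan,
            "specificity": tn / (tn + fp) if tn + fp > 0 else np.nan,
            "precision": tp / (tp + fp) if tp + fp > 0 else np.nan,
        })
    per_class = pd.DataFrame(rows).set_index("class")
    if per_class["recall"].isna().any():
        warnings.warn("empty class row; macro averages skip undefined classes",
                      UserWarning)

    if positive_class is not None:
        if positive_class not in cm.classes:
            raise DataError(f"positive class {positive_class!r} not in matrix")
        if len(cm.classes) != 2:
            raise DataError("positive_class is only meaningful for binary matrices")
        neg = next(c for c in cm.classes if c != positive_class)
        se = float(per_class.loc[positive_class, "recall"])
        sp = float(per_class.loc[neg, "recall"])
        pre = float(per_class.loc[positive_class, "precision"])
    else:
        se = float(per_class["recall"].mean(skipna=True))
        sp = float(per_class["specificity"].mean(skipna=True))
        pre = float(per_class["precision"].mean(skipna=True))
    return MetricsReport(accuracy=acc, sensitivity=se, specificity=sp,
                         precision=pre, per_class=per_class,
                         positive_class=positive_class)


def roc_auc(scores, truth, positive_class) -> tuple[pd.DataFrame, float]:
    """ROC points (threshold sweep over unique scores) and trapezoid AUC.

    AUC equals the normalized Mann-Whitney pair count: the probability
    that a random positive outscores a random negative (ties count 1/2).
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    pos = truth == positive_class
    if pos.all() or not pos.any():
        raise DataError("both classes must be present for a ROC curve")
    fpr, tpr, thresholds = _sk_roc_curve(pos.astype(int), scores)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})
    auc = float(np.trapezoid(tpr, fpr))
    return points, auc


def group_ttest(values, groups) -> tuple[float, float]:
    """Welch two-sample two-sided t-test between exactly two groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if uniq.size != 2:
        raise DataError(f"expected exactly 2 groups, got {uniq.size}")
    a = values[groups == uniq[0]]
    b = values[groups == uniq[1]]
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 samples")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise DataError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def loocv(
    X: np.ndarray,
    labels,
    fit: Callable[[np.ndarray, list], object],
    *,
    score_fn: Callable[[object, np.ndarray], np.ndarray] | None = None,
) -> tuple[list[str], np.ndarray | None]:
    """Generic leave-one-out loop.

    ``fit(Xtrain, ytrain)`` must return a model with a
    ``predict(Xnew) -> list[str]`` method; pretreatment is the fitter's
    responsibility so each fold refits it on training rows only.
    ``score_fn(model, Xnew)`` optionally collects continuous per-class
    scores for ROC analysis. Fold errors propagate with the sample id.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    n = X.shape[0]
    if n < len(set(labels)) + 1:
        raise DataError("need more samples than classes for LOOCV")
    preds: list[str] = []
    scores: list[np.ndarray] = []
    for i in range(n):
        keep = np.arange(n) != i
        try:
            model = fit(X[keep], [labels[j] for j in range(n) if keep[j]])
        except Exception as exc:
            raise DataError(f"LOOCV fold for sample index {i} failed: {exc}") from exc
        preds.append(model.predict(X[i: i + 1])[0])
        if score_fn is not None:
            scores.append(np.asarray(score_fn(model, X[i: i + 1])).ravel())
    return preds, (np.vstack(scores) if score_fn is not None else None)
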