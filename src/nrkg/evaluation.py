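"""Classifier metrics and the preference-fit correlation analysis.

AUC is the tie-aware rank statistic (probability a random positive
outscores a random negative, ties half-credited), equivalent to the
trapezoidal area under the ROC curve; both forms are provided.
Accuracy, precision, recall and F1 come from thresholded scores. The fit
analysis correlates each user's raw-scale 7-component preference profile
with the nutrient vector of a recipe via the Pearson coefficient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import RecipeTable, NUTRIENT_COLUMNS

logger = logging.getLogger(__name__)


def _check_binary(labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if not np.isin(classes, (0, 1)).all():
        raise ValueError(f"labels must be binary 0/1, got {classes}")
    if len(classes) < 2:
        raise ValueError("AUC undefined: only one class present")


def auc(scores, labels) -> float:
    """Tie-aware AUC: mean rank of positives among all scores.

    Equivalent to the Mann-Whitney statistic
    ``(#concordant + 0.5 #tied) / (n_pos * n_neg)`` and to the trapezoidal
    area under the ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(labels)
    order = np.argsort(scores, kind="mergesort")
    ranks = np.empty(len(scores))
    sorted_scores = scores[order]
    # average ranks over tied groups (1-based)
    i = 0
    pos = 1.0
    while i < len(scores):
        j = i
        while j + 1 < len(scores) and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i : j + 1]] = (pos + (pos + (j - i))) / 2.0
        pos += j - i + 1
        i = j + 1
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def auc_trapezoid(scores, labels) -> float:
    """Area under the ROC curve by the trapezoid rule.

    Thresholds sweep the distinct scores descending; tied scores cross the
    threshold simultaneously, so ties contribute diagonal segments whose
    trapezoids equal the half-credit of the rank statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    _check_binary(labels)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = labels[order]
    distinct = np.flatnonzero(np.r_[np.diff(s) != 0, True])
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / tp[-1]]
    fpr = np.r_[0.0, fp / fp[-1]]
    return float(np.trapezoid(tpr, fpr))


@dataclass
class MetricReport:
    """Thresholded confusion counts and the derived metrics."""

    auc: float
    acc: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "acc": self.acc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "threshold": self.threshold,
        }


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int,
                        threshold: float = 0.5, auc_value: float = float("nan")) -> MetricReport:
    """Derive ACC/precision/recall/F1 from confusion counts.

    Zero denominators yield 0 by convention (logged).
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / total
    if tp + fp == 0:
        logger.info("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no actual positives; recall set to 0")
        recall = 0.0
    else:
        recall = tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricReport(
        auc=auc_value, acc=acc, precision=precision, recall=recall, f1=f1,
        tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn), threshold=threshold,
    )


def confusion_metrics(scores, labels, threshold: float = 0.5) -> MetricReport:
    """Threshold scores at ``threshold`` (>=) and report all metrics."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.size == 0:
        raise ValueError("empty prediction batch")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    try:
        auc_value = auc(scores, labels)
    except ValueError:
        auc_value = float("nan")
    return metrics_from_counts(tp, fp, tn, fn, threshold=threshold, auc_value=auc_value)


def pearson(x, y) -> float:
    """Pearson correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0.0 or sy == 0.0:
        raise ValueError("pearson undefined for a constant vector")
    return float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))


@dataclass
class FitRecord:
    """One user-recipe nutritional-fit measurement."""

    user_id: object
    profile: np.ndarray
    recipe_id: object
    recipe_nutrients: np.ndarray
    rho: float


def fit_analysis(profiles: pd.DataFrame, pairs, recipes: RecipeTable) -> list:
    """Pearson fit between raw-scale profiles and recipe nutrient vectors.

    ``profiles`` is the raw-scale per-user table (canonical nutrient
    columns); ``pairs`` is a list of (user_id, recipe_id).
    """
    out = []
    for user, recipe in pairs:
        if user not in profiles.index:
            raise KeyError(f"no profile for user {user!r}")
        p = profiles.loc[user, list(NUTRIENT_COLUMNS)].to_numpy(dtype=float)
        z = recipes.vector(recipe)
        out.append(FitRecord(user, p, recipe, z, pearson(p, z)))
    return out
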