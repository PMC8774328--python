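"""Evaluation metrics: per-class F1, support-weighted F1 (WF1S), accuracy, AUC.

WF1S = sum_i SM_i * F1S_i / sum_i SM_i, where SM_i is the support of
class i and F1S_i = 2 TP / (2 TP + FP + FN) from one-vs-rest counts.
Standard computations are delegated to scikit-learn behind this surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as _skm

from .exceptions import InvalidInputError, UndefinedMetricError


@dataclass
class ClassCounts:
    """One-vs-rest confusion tallies, one entry per class."""

    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    support: np.ndarray
    c: int


def _check_labels(y_true, y_pred, c=None):
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise InvalidInputError("y_true and y_pred must be equal-length 1-D arrays")
    if y_true.size == 0:
        raise InvalidInputError("empty input")
    if c is not None and ((y_true >= c).any() or (y_pred >= c).any()
                          or (y_true < 0).any() or (y_pred < 0).any()):
        raise InvalidInputError(f"labels must lie in 0..{c - 1}")
    return y_true, y_pred


def confusion_counts(y_true, y_pred, c: int) -> ClassCounts:
    """Per-class TP/FP/FN/TN via one-vs-rest tallies."""
    y_true, y_pred = _check_labels(y_true, y_pred, c)
    mcm = _skm.multilabel_confusion_matrix(y_true, y_pred, labels=np.arange(c))
    return ClassCounts(
        tp=mcm[:, 1, 1], fp=mcm[:, 0, 1], fn=mcm[:, 1, 0], tn=mcm[:, 0, 0],
        support=np.bincount(y_true, minlength=c), c=c,
    )


def f1_score(tp: int, fp: int, fn: int) -> float:
    """Harmonic mean of precision and recall from counts; 0 when undefined."""
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 2.0 * tp / denom


def weighted_f1(y_true, y_pred, c: int) -> float:
    """Support-weighted mean of per-class F1 scores."""
    y_true, y_pred = _check_labels(y_true, y_pred, c)
    return float(
        _skm.f1_score(y_true, y_pred, labels=np.arange(c), average="weighted",
                      zero_division=0)
    )


def accuracy(y_true, y_pred) -> float:
    """Fraction of correctly predicted instances."""
    y_true, y_pred = _check_labels(y_true, y_pred)
    return float(_skm.accuracy_score(y_true, y_pred))


def auc(y_true, scores) -> float:
    """Rank-statistic AUC: P(random positive outranks random negative), ties half."""
    y_true = np.asarray(y_true, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise InvalidInputError("labels and scores must be equal-length 1-D arrays")
    if len(np.unique(y_true)) < 2:
        raise UndefinedMetricError("AUC needs both classes present")
    return float(_skm.roc_auc_score(y_true, scores))


def report(y_true, y_pred, c: int, scores=None) -> dict:
    """Bundle WF1S, accuracy, per-class F1 and (binary, if scores given) AUC."""
    counts = confusion_counts(y_true, y_pred, c)
    per_class = [f1_score(counts.tp[i], counts.fp[i], counts.fn[i]) for i in range(c)]
    out = {
        "wf1s": weighted_f1(y_true, y_pred, c),
        "accuracy": accuracy(y_true, y_pred),
        "per_class_f1": per_class,
    }
    if scores is not None and c == 2:
        out["auc"] = auc(y_true, scores)
    return out
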