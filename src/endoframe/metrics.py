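"""Multiclass evaluation: confusion matrix, accuracy, macro F1, multiclass
MCC, macro sensitivity/specificity and one-vs-rest AUC-ROC.

Conventions (logged, not silently applied): per-class quantities with an
empty denominator contribute 0 to macro averages; an MCC denominator of 0
yields 0; AUC skips classes absent from the labels with a warning.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "confusion",
    "accuracy",
    "f1_macro",
    "sensitivity_macro",
    "specificity_macro",
    "mcc",
    "auc_roc_ovr",
    "MetricsReport",
    "report",
]

#: Column order of the serialized report.
REPORT_COLUMNS = ("accuracy", "f1", "mcc", "sensitivity", "specificity", "auc_roc")


def confusion(labels, predictions, n_classes: int) -> np.ndarray:
    """counts[i, j] = number of samples with truth i predicted as j."""
    labels = np.asarray(labels, dtype=int)
    predictions = np.asarray(predictions, dtype=int)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must have equal length")
    if labels.size and (
        labels.min() < 0
        or labels.max() >= n_classes
        or predictions.min() < 0
        or predictions.max() >= n_classes
    ):
        raise ValueError("label outside [0, n_classes)")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (labels, predictions), 1)
    return cm


def _check_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.size == 0 or cm.sum() == 0:
        raise ValueError("empty confusion matrix")
    return cm


def _per_class(cm: np.ndarray):
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return tp, fp, fn, tn


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    out = np.zeros_like(num, dtype=float)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    if not ok.all():
        logger.info("%s: %d class(es) with empty denominator contribute 0", what, (~ok).sum())
    return out


def accuracy(cm: np.ndarray) -> float:
    cm = _check_cm(cm)
    return float(np.trace(cm) / cm.sum())


def f1_macro(cm: np.ndarray) -> float:
    cm = _check_cm(cm)
    tp, fp, fn, _ = _per_class(cm)
    f1 = _safe_div(2 * tp, 2 * tp + fp + fn, "f1")
    return float(f1.mean())


def sensitivity_macro(cm: np.ndarray) -> float:
    cm = _check_cm(cm)
    tp, _, fn, _ = _per_class(cm)
    return float(_safe_div(tp, tp + fn, "sensitivity").mean())


def specificity_macro(cm: np.ndarray) -> float:
    cm = _check_cm(cm)
    _, fp, _, tn = _per_class(cm)
    return float(_safe_div(tn, tn + fp, "specificity").mean())


def mcc(cm: np.ndarray) -> float:
    """Matthews correlation coefficient, multiclass covariance form.

    Reduces to (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) for two
    classes; returns 0 when the denominator vanishes.
    """
    cm = _check_cm(cm).astype(float)
    n = cm.sum()
    t = cm.sum(axis=1)  # truth totals
    p = cm.sum(axis=0)  # prediction totals
    c = np.trace(cm)
    cov_tp = c * n - t @ p
    cov_pp = n * n - p @ p
    cov_tt = n * n - t @ t
    den = np.sqrt(cov_pp * cov_tt)
    if den == 0:
        return 0.0
    return float(cov_tp / den)


def auc_roc_ovr(probs: np.ndarray, labels) -> float:
    """Macro one-vs-rest AUC via the rank (Mann-Whitney) statistic."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.shape[0] != labels.shape[0]:
        raise ValueError("probs rows must align with labels")
    aucs = []
    for c in range(probs.shape[1]):
        pos = labels == c
        n_pos = int(pos.sum())
        n_neg = int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {c} absent from labels; skipped in AUC", stacklevel=2)
            continue
        ranks = rankdata(probs[:, c])
        u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
        aucs.append(u / (n_pos * n_neg))
    if not aucs:
        raise ValueError("no class present in labels")
    return float(np.mean(aucs))


@dataclass(frozen=True)
class MetricsReport:
    """One evaluation record, serialized in a fixed column order."""

    accuracy: float
    f1: float
    mcc: float
    sensitivity: float
    specificity: float
    auc_roc: float

    def to_dict(self) -> dict[str, float]:
        d = asdict(self)
        return {k: d[k] for k in REPORT_COLUMNS}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        return cls(**json.loads(s))


def report(cm: np.ndarray, probs: np.ndarray, labels) -> MetricsReport:
    """All six metrics from one confusion matrix and probability matrix."""
    return MetricsReport(
        accuracy=accuracy(cm),
        f1=f1_macro(cm),
        mcc=mcc(cm),
        sensitivity=sensitivity_macro(cm),
        specificity=specificity_macro(cm),
        auc_roc=auc_roc_ovr(probs, labels),
    )
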