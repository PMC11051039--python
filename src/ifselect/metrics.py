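"""Multiclass evaluation metrics for imbalanced classification.

Two points here differ from the most common library conventions and are
deliberate:

* ``weighted_f1`` is the harmonic mean of the class-share-weighted precision
  and the class-share-weighted recall — not the weighted average of
  per-class F1 scores. The latter (scikit-learn's ``average="weighted"``)
  is available as :func:`weighted_f1_classic`.
* ``mcc`` is the multiclass Matthews correlation coefficient computed as the
  correlation between the n × L one-hot indicator matrices of true and
  predicted classes (Gorodkin's R_K): cov(X, Y) summed over indicator
  columns, normalized by sqrt(cov(X, X) · cov(Y, Y)). For L = 2 this equals
  the classical binary MCC.

Per-class precision with an empty prediction column (TP + FP = 0) is defined
as 0 and logged, keeping the weighted sums finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class ConfusionSummary:
    """Per-class TP/FP/FN counts plus class-share weights.

    ``w[i]`` is the share of truly-class-i samples among all n samples;
    weights sum to 1 (classes absent from the data get weight 0).
    """

    class_names: list[str]
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    n: int

    @property
    def L(self) -> int:
        return len(self.class_names)

    @property
    def w(self) -> np.ndarray:
        return (self.tp + self.fn) / float(self.n)

    def precision(self) -> np.ndarray:
        denom = self.tp + self.fp
        out = np.zeros(self.L)
        empty = denom == 0
        if empty.any():
            logger.debug(
                "precision undefined (TP+FP=0) for classes %s; defined as 0",
                [self.class_names[i] for i in np.flatnonzero(empty)],
            )
        np.divide(self.tp, denom, out=out, where=~empty)
        return out

    def recall(self) -> np.ndarray:
        denom = self.tp + self.fn
        out = np.zeros(self.L)
        np.divide(self.tp, denom, out=out, where=denom > 0)
        return out

    def per_class_f1(self) -> np.ndarray:
        p, r = self.precision(), self.recall()
        out = np.zeros(self.L)
        denom = p + r
        np.divide(2 * p * r, denom, out=out, where=denom > 0)
        return out


@dataclass
class MetricReport:
    """Bundle of the four headline metrics plus per-class breakdown."""

    weighted_f1: float
    macro_f1: float
    acc: float
    mcc: float
    class_names: list[str] = field(default_factory=list)
    precision_per_class: list[float] = field(default_factory=list)
    recall_per_class: list[float] = field(default_factory=list)
    f1_per_class: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "weighted_f1": self.weighted_f1,
            "macro_f1": self.macro_f1,
            "acc": self.acc,
            "mcc": self.mcc,
            "classes": list(self.class_names),
            "precision_per_class": list(self.precision_per_class),
            "recall_per_class": list(self.recall_per_class),
            "f1_per_class": list(self.f1_per_class),
        }


def _check_labels(true_labels, pred_labels, class_names) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(pred_labels, dtype=object)
    if len(t) != len(p):
        raise ValueError(f"label vectors differ in length: {len(t)} vs {len(p)}")
    if len(t) == 0:
        raise ValueError("empty label vectors")
    known = set(class_names)
    bad = sorted({x for x in np.concatenate([t, p]).tolist() if x not in known})
    if bad:
        raise ValueError(f"labels not in class_names: {bad}")
    return t, p


def confusion(true_labels, pred_labels, class_names) -> ConfusionSummary:
    """Per-class TP/FP/FN summary of a prediction vector."""
    t, p = _check_labels(true_labels, pred_labels, class_names)
    index = {c: i for i, c in enumerate(class_names)}
    ti = np.array([index[x] for x in t])
    pi = np.array([index[x] for x in p])
    L = len(class_names)
    table = np.zeros((L, L), dtype=int)  # rows: true, cols: predicted
    np.add.at(table, (ti, pi), 1)
    tp = np.diag(table).astype(int)
    fp = table.sum(axis=0) - tp
    fn = table.sum(axis=1) - tp
    return ConfusionSummary(
        class_names=list(class_names), tp=tp, fp=fp, fn=fn, n=len(t)
    )


def weighted_precision(summary: ConfusionSummary) -> float:
    return float(np.dot(summary.w, summary.precision()))


def weighted_recall(summary: ConfusionSummary) -> float:
    return float(np.dot(summary.w, summary.recall()))


def weighted_f1(summary: ConfusionSummary) -> float:
    """Harmonic mean of class-share-weighted precision and recall."""
    p = weighted_precision(summary)
    r = weighted_recall(summary)
    if p + r == 0:
        logger.debug("weighted_f1 degenerate: weighted precision and recall both 0")
        return 0.0
    return 2.0 * p * r / (p + r)


def weighted_f1_classic(summary: ConfusionSummary) -> float:
    """Class-share-weighted average of per-class F1 (the common convention)."""
    return float(np.dot(summary.w, summary.per_class_f1()))


def macro_f1(summary: ConfusionSummary) -> float:
    """Unweighted mean of per-class F1 over classes present in the data."""
    present = (summary.tp + summary.fp + summary.fn) > 0
    if not present.any():
        return 0.0
    return float(summary.per_class_f1()[present].mean())


def acc(true_labels, pred_labels) -> float:
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(pred_labels, dtype=object)
    if len(t) != len(p) or len(t) == 0:
        raise ValueError("label vectors must be nonempty and equal length")
    return float(np.mean(t == p))


def mcc(true_labels, pred_labels, class_names) -> float:
    """Multiclass MCC: correlation of one-hot true and predicted indicators."""
    t, p = _check_labels(true_labels, pred_labels, class_names)
    index = {c: i for i, c in enumerate(class_names)}
    n, L = len(t), len(class_names)
    X = np.zeros((n, L))
    Y = np.zeros((n, L))
    X[np.arange(n), [index[x] for x in t]] = 1.0
    Y[np.arange(n), [index[x] for x in p]] = 1.0
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float(np.sum(Xc * Yc))
    cov_xx = float(np.sum(Xc * Xc))
    cov_yy = float(np.sum(Yc * Yc))
    if cov_xx == 0 or cov_yy == 0:
        logger.debug("mcc degenerate: constant indicator matrix; returning 0")
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def evaluate(true_labels, pred_labels, class_names) -> MetricReport:
    """All metrics from one pooled prediction vector."""
    summary = confusion(true_labels, pred_labels, class_names)
    return MetricReport(
        weighted_f1=weighted_f1(summary),
        macro_f1=macro_f1(summary),
        acc=acc(true_labels, pred_labels),
        mcc=mcc(true_labels, pred_labels, class_names),
        class_names=list(class_names),
        precision_per_class=[float(x) for x in summary.precision()],
        recall_per_class=[float(x) for x in summary.recall()],
        f1_per_class=[float(x) for x in summary.per_class_f1()],
    )
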