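"""Classifier evaluation: confusion matrices, threshold metrics, AUC, and
stage/transition distribution bookkeeping.

Undefined metrics (zero denominators, single-class AUC) are reported as
missing (`nan`) rather than silently mapped to 0.  Summary values are
rounded half-up to two decimals; raw values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyInputError, SchemaError, UndefinedMetricError
from .segmentation import round_half_up


@dataclass
class ConfusionMatrix:
    tn: int
    fp: int
    fn: int
    tp: int

    def __post_init__(self) -> None:
        for name in ("tn", "fp", "fn", "tp"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            setattr(self, name, int(v))
        if self.total == 0:
            raise EmptyInputError("confusion matrix is empty")

    @property
    def total(self) -> int:
        return self.tn + self.fp + self.fn + self.tp


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float = float("nan")

    def rounded(self, ndigits: int = 2) -> "MetricReport":
        vals = {
            k: (round_half_up(v, ndigits) if np.isfinite(v) else v)
            for k, v in self.__dict__.items()
        }
        return MetricReport(**vals)


def confusion(labels, probs, threshold: float = 0.5) -> ConfusionMatrix:
    """Confusion matrix at a probability threshold (ties predict positive)."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise SchemaError("labels and probabilities differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise SchemaError("labels must be binary 0/1")
    pred = probs >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tn=int(np.sum(~pos & ~pred)),
        fp=int(np.sum(~pos & pred)),
        fn=int(np.sum(pos & ~pred)),
        tp=int(np.sum(pos & pred)),
    )


def metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy, precision, recall and F1 from a confusion matrix."""
    nan = float("nan")
    accuracy = (cm.tp + cm.tn) / cm.total
    precision = cm.tp / (cm.tp + cm.fp) if cm.tp + cm.fp > 0 else nan
    recall = cm.tp / (cm.tp + cm.fn) if cm.tp + cm.fn > 0 else nan
    if np.isfinite(precision) and np.isfinite(recall) and precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = nan
    return MetricReport(accuracy=accuracy, precision=precision, recall=recall, f1=f1)


def auc(labels, probs) -> float:
    """Rank-based (Mann-Whitney) AUC; tied scores contribute one half."""
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if labels.shape != probs.shape:
        raise SchemaError("labels and probabilities differ in length")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("AUC needs both classes present")
    ranks = rankdata(probs)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate(labels, probs, threshold: float = 0.5) -> MetricReport:
    """Threshold metrics plus AUC in one report."""
    report = metrics(confusion(labels, probs, threshold))
    report.auc = auc(labels, probs)
    return report


def stage_distribution(table: pd.DataFrame, label_columns=None) -> pd.DataFrame:
    """Counts and percentages of segments carrying each binary label.

    The denominator is the number of segments with at least one of the
    labels; percentages are rounded half-up to two decimals (raw counts are
    returned alongside).
    """
    if label_columns is None:
        label_columns = [
            c for c in table.columns if c.startswith("certain_") or "-" in c
        ]
    if len(table) == 0 or not label_columns:
        raise EmptyInputError("no labeled segments")
    labels = table[list(label_columns)].astype(int)
    counts = labels.sum(axis=0)
    total = int((labels.sum(axis=1) > 0).sum())
    if total == 0:
        raise EmptyInputError("no segment carries any label")
    pct = counts / total * 100.0
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "percent": [round_half_up(v, 2) for v in pct],
        }
    )
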