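"""Binary-classification metrics for site prediction.

ACC, MCC, Sn, Sp, PRE and F1 follow the standard confusion-table formulas;
AUC is the rank statistic (probability that a random positive outscores a
random negative, ties counted half), which equals trapezoidal integration of
the ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricSet:
    ACC: float
    MCC: float
    Sn: float
    Sp: float
    PRE: float
    F1: float
    AUC: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def confusion(labels, probabilities, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts at a probability threshold (prediction 1 iff
    probability >= threshold)."""
    y = np.asarray(labels)
    p = np.asarray(probabilities, dtype=float)
    if y.shape != p.shape:
        raise ValueError("labels and probabilities must have equal length")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (pred == 1))),
        TN=int(np.sum((y == 0) & (pred == 0))),
        FP=int(np.sum((y == 0) & (pred == 1))),
        FN=int(np.sum((y == 1) & (pred == 0))),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Threshold metrics from confusion counts (AUC left unset).

    MCC is defined as 0 when any denominator factor vanishes.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    denom2 = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom2) if denom2 > 0 else 0.0
    return MetricSet(
        ACC=(tp + tn) / c.total,
        MCC=float(mcc),
        Sn=_safe_div(tp, tp + fn),
        Sp=_safe_div(tn, tn + fp),
        PRE=_safe_div(tp, tp + fp),
        F1=_safe_div(2 * tp, 2 * tp + fp + fn),
    )


def auc(labels, scores) -> float:
    """Rank-based AUC (Mann-Whitney with ties counted 1/2)."""
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(s)  # average ranks for ties
    rank_sum = ranks[y == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate_scores(labels, probabilities, threshold: float = 0.5) -> MetricSet:
    """Full metric set (including AUC) from labels and probabilities."""
    c = confusion(labels, probabilities, threshold)
    m = compute_metrics(c)
    return MetricSet(
        ACC=m.ACC, MCC=m.MCC, Sn=m.Sn, Sp=m.Sp, PRE=m.PRE, F1=m.F1,
        AUC=auc(labels, probabilities),
    )
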