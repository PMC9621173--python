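"""Evaluation statistics: AUROC with DeLong confidence intervals, PR and
precision-gain/recall-gain curves, and Kendall tau-b.

The AUROC is computed as the Mann–Whitney statistic
P(score+ > score-) + 0.5 P(tie); its confidence interval uses DeLong's
nonparametric variance built from per-observation placement values (with
midranks for ties), a normal-theory interval truncated to [0, 1].

Precision-gain/recall-gain (PRG) curves re-express precision and recall
relative to the always-positive baseline whose precision equals the
prevalence pi:

    gain(v) = (v - pi) / ((1 - pi) * v)

so a classifier no better than baseline sits at gain 0 and a perfect one at
gain 1; the area is taken over recall gain in [0, 1] with precision gain
floored at 0.  PRG areas are prevalence-adjusted and better suited than
AUPRC when class imbalance differs between settings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import average_precision_score, precision_recall_curve

__all__ = [
    "CurveResult",
    "CIResult",
    "auroc",
    "delong_ci",
    "pr_curve",
    "prg_curve",
    "kendall_tau_b",
]


@dataclass(frozen=True)
class CurveResult:
    """An evaluation curve: ordered (x, y) points and the area under it."""

    points: np.ndarray  # shape (k, 2), sorted by x
    area: float
    kind: str  # {"roc", "pr", "prg"}


@dataclass(frozen=True)
class CIResult:
    estimate: float
    lower: float
    upper: float
    level: float

    def __post_init__(self) -> None:
        if not self.lower <= self.estimate <= self.upper:
            raise ValueError("CI bounds do not bracket the estimate")


def _check_binary(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def _placements(scores, labels):
    """DeLong placement values (midrank form) and the AUROC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(np.concatenate([pos, neg]))
    v_pos = (tz[:m] - tx) / n          # per-positive placement
    v_neg = 1.0 - (tz[m:] - ty) / m    # per-negative placement
    auc = float(v_pos.mean())
    return auc, v_pos, v_neg


def auroc(scores, labels) -> float:
    """Mann–Whitney AUROC: P(score+ > score-) + 0.5 P(tie)."""
    scores, labels = _check_binary(scores, labels)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("both classes must be present")
    auc, _, _ = _placements(scores, labels)
    return auc


def delong_ci(scores, labels, level: float = 0.95) -> CIResult:
    """Normal-theory AUROC confidence interval with DeLong's variance.

    The variance is ``var(v+)/m + var(v-)/n`` over the per-observation
    placement values.  A perfectly separated sample has zero estimated
    variance; a degenerate zero-width interval is returned with a warning.
    """
    scores, labels = _check_binary(scores, labels)
    m = int(labels.sum())
    n = len(labels) - m
    if m < 2 or n < 2:
        raise ValueError("need at least 2 observations per class")
    auc, v_pos, v_neg = _placements(scores, labels)
    var = v_pos.var(ddof=1) / m + v_neg.var(ddof=1) / n
    if var <= 0.0:
        if auc in (0.0, 1.0):
            warnings.warn("perfect separation: degenerate zero-width CI",
                          stacklevel=2)
            return CIResult(auc, auc, auc, level)
        # var(v+) and var(v-) can only both vanish with all placements
        # constant, which forces auc to 0 or 1; guard anyway.
        var = 0.0
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    return CIResult(auc, max(0.0, auc - half), min(1.0, auc + half), level)


def pr_curve(scores, labels) -> CurveResult:
    """Precision–recall curve; area by average precision (no interpolation)."""
    scores, labels = _check_binary(scores, labels)
    if labels.sum() == 0:
        raise ValueError("no positive labels")
    precision, recall, _ = precision_recall_curve(labels, scores)
    pts = np.column_stack([recall[::-1], precision[::-1]])  # sort by recall
    ap = float(average_precision_score(labels, scores))
    return CurveResult(points=pts, area=ap, kind="pr")


def _operating_points(scores, labels):
    """(recall, precision) at every distinct threshold, descending score."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep the last index of each tied-score block
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    P = labels.sum()
    recall = tp / P
    precision = tp / (tp + fp)
    return recall, precision


def prg_curve(scores, labels) -> CurveResult:
    """Precision-gain/recall-gain curve and its area over recall gain [0, 1]."""
    scores, labels = _check_binary(scores, labels)
    P = int(labels.sum())
    if P == 0 or P == len(labels):
        raise ValueError("prevalence must be strictly inside (0, 1)")
    pi = P / len(labels)
    recall, precision = _operating_points(scores, labels)

    with np.errstate(divide="ignore", invalid="ignore"):
        rg = np.where(recall > 0, (recall - pi) / ((1 - pi) * recall), -np.inf)
        pg = np.where(precision > 0,
                      (precision - pi) / ((1 - pi) * precision), -np.inf)

    keep = rg >= 0
    if not keep.any():  # cannot happen: the all-positive point has rg = 1
        raise ValueError("no operating point with non-negative recall gain")
    first = int(np.argmax(keep))
    if first > 0 and np.isfinite(pg[first - 1]) and rg[first] > 0:
        # linear interpolation of precision gain at the rg = 0 boundary
        w = (0.0 - rg[first - 1]) / (rg[first] - rg[first - 1])
        pg0 = pg[first - 1] + w * (pg[first] - pg[first - 1])
    else:
        pg0 = pg[first]
    rg_pts = np.r_[0.0, rg[keep]]
    pg_pts = np.r_[pg0, pg[keep]]
    pg_clipped = np.maximum(pg_pts, 0.0)
    area = float(np.trapezoid(pg_clipped, rg_pts))
    return CurveResult(points=np.column_stack([rg_pts, pg_pts]),
                       area=area, kind="prg")


def kendall_tau_b(x, y) -> float:
    """Kendall tau-b rank correlation with standard tie corrections.

    Returns NaN (with a warning) when either vector is constant, where the
    statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D arrays of length >= 2")
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        warnings.warn("tau-b undefined for a constant vector", stacklevel=2)
        return float("nan")
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)
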