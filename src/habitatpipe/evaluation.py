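"""Model evaluation: ROC/AUC, Youden operating point, confusion metrics,
the DeLong test for correlated ROC curves, and decision-curve analysis.

The AUC is the Mann-Whitney probability that a random responder outranks a
random non-responder, with ties counted 1/2 (computed from midranks, so it
equals trapezoidal ROC integration exactly).  Confidence intervals and the
correlated-AUC comparison use DeLong's structural components: for every
positive case the component is its placement value against the negatives and
vice versa; the empirical covariance of these components yields the variance
of an AUC or of a difference of AUCs evaluated on the same cases.

Decision-curve analysis reports, for a grid of threshold probabilities pt,
the net benefit NB(pt) = TP/n - FP/n * pt/(1-pt) of treating cases whose
predicted probability is >= pt (the closed-on-the-positive-side convention
used throughout), against the treat-all and treat-none policies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ROCResult",
    "ConfusionMetrics",
    "DeLongResult",
    "DCACurve",
    "roc_auc",
    "youden_cutoff",
    "confusion_metrics",
    "reconstruct_confusion",
    "delong_test",
    "decision_curve",
]


# ---------------------------------------------------------------------------
# DeLong machinery


def _placement_components(scores: np.ndarray, labels: np.ndarray):
    """Midrank placement values of positives vs negatives and vice versa."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = sps.rankdata(np.concatenate([pos, neg]))
    pos_ranks = sps.rankdata(pos)
    neg_ranks = sps.rankdata(neg)
    # V10[i] = P(pos_i > random neg) with ties 1/2
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def _check_binary(labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes, coded 0/1")
    return labels


@dataclass
class ROCResult:
    """ROC curve with rank-based AUC and DeLong-variance 95% CI."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    auc_se: float
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, alpha: float = 0.05) -> ROCResult:
    """ROC curve, Mann-Whitney AUC and its DeLong confidence interval.

    Cases are called positive when score >= threshold; thresholds run
    through the sorted unique scores (plus one above the maximum), so the
    curve starts at (0, 0) and ends at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    auc, v10, v01 = _placement_components(scores, labels)
    m, n = v10.size, v01.size
    # with a singleton class the component variance is undefined; report 0
    var = (v10.var(ddof=1) / m if m > 1 else 0.0) \
        + (v01.var(ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    z = sps.norm.ppf(1 - alpha / 2)
    lo, hi = np.clip([auc - z * se, auc + z * se], 0.0, 1.0)

    uniq = np.unique(scores)
    thresholds = np.concatenate([[uniq[-1] + 1.0], uniq[::-1]])
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & (labels == 1)).sum(axis=1) / m
    fpr = (pred & (labels == 0)).sum(axis=1) / n
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
                     ci_low=float(lo), ci_high=float(hi), auc_se=se,
                     n_pos=m, n_neg=n)


def youden_cutoff(roc: ROCResult):
    """Threshold maximizing the Youden index J = sensitivity + specificity - 1.

    Exact ties are resolved to the smallest threshold.
    """
    j = roc.tpr - roc.fpr
    best_j = j.max()
    ties = np.flatnonzero(j == best_j)
    # thresholds are in descending order: the last tie is the smallest
    k = ties[-1]
    return float(roc.thresholds[k]), {"youden": float(best_j),
                                      "sensitivity": float(roc.tpr[k]),
                                      "specificity": float(1 - roc.fpr[k])}


# ---------------------------------------------------------------------------
# Confusion metrics


@dataclass
class ConfusionMetrics:
    """The confusion-matrix metric battery of a binary operating point."""

    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float = field(init=False)
    specificity: float = field(init=False)
    ppv: float = field(init=False)
    npv: float = field(init=False)
    accuracy: float = field(init=False)
    balanced_accuracy: float = field(init=False)
    mcc: float = field(init=False)

    def __post_init__(self):
        tp, fp, tn, fn = self.TP, self.FP, self.TN, self.FN
        if min(tp, fp, tn, fn) < 0 or tp + fp + tn + fn == 0:
            raise ValueError("counts must be nonnegative with n >= 1")
        n = tp + fp + tn + fn
        self.sensitivity = tp / (tp + fn) if tp + fn else np.nan
        self.specificity = tn / (tn + fp) if tn + fp else np.nan
        self.ppv = tp / (tp + fp) if tp + fp else np.nan
        self.npv = tn / (tn + fn) if tn + fn else np.nan
        self.accuracy = (tp + tn) / n
        self.balanced_accuracy = (self.sensitivity + self.specificity) / 2
        den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        # zero denominator -> 0 by convention
        self.mcc = float((tp * tn - fp * fn) / den) if den > 0 else 0.0


def confusion_metrics(TP: int, FP: int, TN: int, FN: int) -> ConfusionMetrics:
    """Standard metric battery from the four confusion counts."""
    return ConfusionMetrics(TP=int(TP), FP=int(FP), TN=int(TN), FN=int(FN))


def reconstruct_confusion(sensitivity: float, specificity: float,
                          n_pos: int, n_neg: int) -> ConfusionMetrics:
    """Recover integer confusion counts from printed sensitivity/specificity.

    Searches TP in 0..n_pos and TN in 0..n_neg for the counts whose rates,
    rounded to 3 decimals, best match the printed values (closest match on
    ties at lower counts).  Useful for auditing published metric tables.
    """
    best, best_err = None, np.inf
    for tp in range(n_pos + 1):
        for tn in range(n_neg + 1):
            err = (round(tp / n_pos, 3) - sensitivity) ** 2 \
                + (round(tn / n_neg, 3) - specificity) ** 2
            if err < best_err:
                best, best_err = (tp, tn), err
    tp, tn = best
    return confusion_metrics(TP=tp, FP=n_neg - tn, TN=tn, FN=n_pos - tp)


# ---------------------------------------------------------------------------
# DeLong test


@dataclass
class DeLongResult:
    auc_a: float
    auc_b: float
    difference: float
    var_difference: float
    z: float
    p_value: float


def delong_test(scores_a, scores_b, labels) -> DeLongResult:
    """DeLong comparison of two correlated AUCs evaluated on the same cases.

    Uses the midrank structural components of both score vectors; the
    variance of the AUC difference accounts for their correlation.  A model
    compared with itself (zero variance) returns p = 1.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if scores_a.shape != labels.shape or scores_b.shape != labels.shape:
        raise ValueError("both score vectors must cover the same cases")
    auc_a, v10a, v01a = _placement_components(scores_a, labels)
    auc_b, v10b, v01b = _placement_components(scores_b, labels)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var)
        p = float(2 * sps.norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, difference=float(diff),
                        var_difference=float(max(var, 0.0)), z=float(z),
                        p_value=min(max(p, np.finfo(float).tiny), 1.0))


# ---------------------------------------------------------------------------
# Decision curve analysis


@dataclass
class DCACurve:
    thresholds: np.ndarray
    net_benefit: np.ndarray
    treat_all: np.ndarray
    treat_none: np.ndarray
    prevalence: float


def decision_curve(probabilities, labels, thresholds=None) -> DCACurve:
    """Net benefit of acting on predicted probabilities across thresholds.

    NB(pt) = TP(pt)/n - FP(pt)/n * pt/(1-pt) with positivity called at
    probability >= pt.  The grid defaults to 0.01..0.60 in steps of 0.01;
    pt = 1 is excluded by construction.
    """
    p = np.asarray(probabilities, dtype=float)
    labels = _check_binary(labels)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 0.601, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = labels.size
    prev = labels.mean()
    odds = thresholds / (1 - thresholds)
    pred = p[None, :] >= thresholds[:, None]
    tp = (pred & (labels == 1)).sum(axis=1) / n
    fp = (pred & (labels == 0)).sum(axis=1) / n
    nb = tp - fp * odds
    treat_all = prev - (1 - prev) * odds
    return DCACurve(thresholds=thresholds, net_benefit=nb,
                    treat_all=treat_all, treat_none=np.zeros_like(thresholds),
                    prevalence=float(prev))
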