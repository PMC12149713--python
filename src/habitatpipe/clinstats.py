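"""Group-comparison statistics for clinical covariate tables.

Categorical covariates are compared between responders and non-responders
with the Pearson chi-square test (optionally Yates continuity-corrected);
continuous covariates use the pooled-variance two-sample t-test when both
groups pass a Shapiro-Wilk normality pre-check, and the Mann-Whitney U test
(normal approximation with tie correction) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparisonResult", "pearson_chi2", "compare_groups"]


@dataclass(frozen=True)
class GroupComparisonResult:
    """A named test statistic with its p-value and method flag."""

    statistic_name: str
    statistic: float
    p_value: float
    method: str


def pearson_chi2(table, correction: bool = False) -> GroupComparisonResult:
    """Pearson chi-square test of independence on an r x c count table.

    ``correction=True`` applies the Yates continuity correction (2x2 tables
    only).  Zero row or column margins raise.
    """
    t = np.asarray(table)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0) or not np.issubdtype(np.asarray(t).dtype, np.number):
        raise ValueError("table must hold nonnegative counts")
    if np.any(t != np.floor(t)):
        raise ValueError("table must hold integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined")
    if correction and t.shape != (2, 2):
        raise ValueError("continuity correction applies to 2x2 tables only")
    res = sps.chi2_contingency(t, correction=correction)
    return GroupComparisonResult(
        statistic_name="chi2", statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="pearson_chi2_corrected" if correction else "pearson_chi2")


def compare_groups(x, y, method: str = "auto") -> GroupComparisonResult:
    """Compare a continuous variable between two groups.

    ``method`` is 't' (pooled-variance Student t), 'mann_whitney' (normal
    approximation with tie correction) or 'auto' (Shapiro-Wilk pre-check on
    both groups at p > 0.05 selects the t-test).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if method not in ("auto", "t", "mann_whitney"):
        raise ValueError("method must be auto, t or mann_whitney")
    if method == "auto":
        normal = all(sps.shapiro(g).pvalue > 0.05 for g in (x, y)
                     if np.ptp(g) > 0)
        method = "t" if normal else "mann_whitney"
    if method == "t":
        res = sps.ttest_ind(x, y, equal_var=True)
        return GroupComparisonResult("t", float(res.statistic),
                                     float(res.pvalue), "student_t_pooled")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return GroupComparisonResult("U", float(res.statistic),
                                 float(res.pvalue), "mann_whitney_u")
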