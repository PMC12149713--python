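"""Staged radiomics feature selection.

The chain applied to the training feature table, in order:

1. **Reproducibility (ICC) filter** — when a second rater's segmentation is
   available, features whose two-way random-effects absolute-agreement
   single-rater ICC across the raters falls below 0.75 are discarded as
   segmentation-sensitive.
2. **z-score normalization** — every feature is centered and scaled with the
   training-set mean and standard deviation; test rows reuse the training
   statistics.  Constant training columns are dropped.
3. **Pearson redundancy filter** — a greedy scan in deterministic column
   order drops the later member of any pair with |r| > 0.9.
4. **LASSO** — an L1-penalized least-squares fit of the binary outcome with
   the penalty chosen on an exponentially spaced grid (0.005-0.05) by 5-fold
   cross-validation; features with nonzero coefficients survive.
5. **RFE** — recursive feature elimination with a logistic estimator,
   dropping the smallest-|coefficient| feature per round (ties drop the
   later column) until the target count remains; the target count is itself
   chosen by cross-validated AUC over a small range.

Each stage's survivors are a subset of the previous stage's, and the whole
chain is reproducible from its seed via the SelectionReport.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LassoCV, LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold

__all__ = [
    "icc_2_1",
    "icc_filter",
    "zscore_normalize",
    "ZScoreNormalizer",
    "pearson_filter",
    "lasso_alpha_grid",
    "lasso_select",
    "rfe_select",
    "choose_rfe_target",
    "run_selection",
    "SelectionReport",
]


# ---------------------------------------------------------------------------
# ICC(2,1)


def icc_2_1(ratings: np.ndarray) -> float:
    """Two-way random-effects, absolute-agreement, single-rater ICC.

    ``ratings`` is an (n subjects x k raters) matrix.  Uses the classical
    mean-squares decomposition:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the residual
    mean square.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("ratings must be (n >= 3 subjects) x (k >= 2 raters)")
    if not np.isfinite(x).all():
        raise ValueError("ratings must be finite")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)
    ssr = k * ((row_m - grand) ** 2).sum()
    ssc = n * ((col_m - grand) ** 2).sum()
    sse = ((x - row_m[:, None] - col_m[None, :] + grand) ** 2).sum()
    sst = ((x - grand) ** 2).sum()
    if sst == 0:
        raise ValueError("zero total variance: ICC undefined")
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def icc_filter(features_rater1: pd.DataFrame, features_rater2: pd.DataFrame,
               threshold: float = 0.75) -> tuple[list, dict]:
    """Keep features whose between-rater ICC(2,1) is >= threshold.

    Returns ``(retained_names, icc_by_feature)``.  Features constant across
    both raters carry no segmentation information either way and are kept
    (their ICC is undefined).
    """
    if list(features_rater1.columns) != list(features_rater2.columns):
        raise ValueError("rater tables must have identical columns")
    if not features_rater1.index.equals(features_rater2.index):
        raise ValueError("rater tables must cover the same cases")
    retained, iccs = [], {}
    for col in features_rater1.columns:
        pair = np.column_stack([features_rater1[col].to_numpy(float),
                                features_rater2[col].to_numpy(float)])
        pair = pair[np.isfinite(pair).all(axis=1)]
        if pair.shape[0] < 3:
            continue
        try:
            val = icc_2_1(pair)
        except ValueError:
            retained.append(col)
            iccs[col] = np.nan
            continue
        iccs[col] = val
        if val >= threshold:
            retained.append(col)
    return retained, iccs


# ---------------------------------------------------------------------------
# z-score normalization


class ZScoreNormalizer(BaseEstimator, TransformerMixin):
    """Center/scale features with training-set statistics.

    Constant training columns are dropped (recorded in ``dropped_``); the
    transform of any table uses the training mean/std, so only training
    columns are guaranteed mean 0 / sd 1.
    """

    def fit(self, X: pd.DataFrame, y=None):
        X = pd.DataFrame(X)
        mean = X.mean(axis=0)
        std = X.std(axis=0, ddof=0)
        self.dropped_ = list(std.index[std == 0])
        keep = std.index[std > 0]
        self.columns_ = list(keep)
        self.mean_ = mean[keep]
        self.std_ = std[keep]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        return (X[self.columns_] - self.mean_) / self.std_


def zscore_normalize(table: pd.DataFrame, stats=None):
    """Functional form: fit-transform when ``stats`` is None, else apply
    ``(mean, std)`` Series from a training fit."""
    if stats is None:
        norm = ZScoreNormalizer().fit(table)
        return norm.transform(table), (norm.mean_, norm.std_)
    mean, std = stats
    return (table[mean.index] - mean) / std


# ---------------------------------------------------------------------------
# Pearson redundancy filter


def pearson_filter(table: pd.DataFrame, cutoff: float = 0.9) -> list:
    """Greedy correlation de-duplication in deterministic column order.

    Scans columns left to right; a column correlated with any already-kept
    column at |r| > cutoff (strict) is dropped.  The retained set therefore
    contains no pair exceeding the cutoff.
    """
    cols = list(table.columns)
    if len(cols) < 2:
        return cols
    X = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    kept_idx = []
    for j in range(len(cols)):
        if all(abs(corr[j, i]) <= cutoff for i in kept_idx):
            kept_idx.append(j)
    return [cols[j] for j in kept_idx]


# ---------------------------------------------------------------------------
# LASSO


def lasso_alpha_grid(lo: float = 0.005, hi: float = 0.05, num: int = 20) -> np.ndarray:
    """Exponentially (geometrically) spaced penalty grid."""
    return np.geomspace(lo, hi, num)


def lasso_select(X: pd.DataFrame, y, alphas=None, folds: int = 5,
                 seed: int = 0) -> tuple[list, float]:
    """L1-penalized least-squares selection of a binary outcome.

    The penalty is chosen on the exponential grid by 5-fold CV (shuffled,
    seeded); features with nonzero coefficients at the chosen penalty are
    returned.  Least-squares loss with 0/1 outcomes mirrors the standard
    LassoCV behaviour; this choice affects the selected set and is therefore
    fixed here.  If the fit shrinks everything to zero the full input is
    passed through (selection deferred to the next stage).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < folds:
        raise ValueError("fewer rows than CV folds")
    alphas = lasso_alpha_grid() if alphas is None else np.asarray(alphas)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(alphas=alphas, cv=cv, max_iter=100_000, tol=1e-3)
    model.fit(X.to_numpy(dtype=float), y)
    mask = np.abs(model.coef_) > 1e-10
    selected = [c for c, m in zip(X.columns, mask) if m]
    if not selected:
        selected = list(X.columns)
    return selected, float(model.alpha_)


# ---------------------------------------------------------------------------
# RFE


def _rfe_ranking(X: np.ndarray, y: np.ndarray, seed: int) -> list:
    """Full elimination order (last eliminated first): repeatedly fit a
    logistic model and drop the smallest-|coefficient| feature; exact ties
    drop the later column."""
    active = list(range(X.shape[1]))
    eliminated = []
    while len(active) > 1:
        est = LogisticRegression(C=1.0, solver="lbfgs",
                                 max_iter=2000, random_state=seed)
        est.fit(X[:, active], y)
        coefs = np.abs(est.coef_[0])
        m = coefs.min()
        ties = np.flatnonzero(coefs == m)
        drop_pos = int(ties[-1])  # later column on ties
        eliminated.append(active.pop(drop_pos))
    ranking = active + eliminated[::-1]  # best first
    return ranking


def rfe_select(X: pd.DataFrame, y, n_target: int, seed: int = 0) -> tuple[list, list]:
    """Recursive feature elimination down to ``n_target`` features.

    Returns ``(selected_names, ranking)`` with the ranking listing all
    features best-first (order of survival).
    """
    X = pd.DataFrame(X)
    y = np.asarray(y)
    p = X.shape[1]
    if not 1 <= n_target <= p:
        raise ValueError("n_target must lie in [1, n_features]")
    ranking_idx = _rfe_ranking(X.to_numpy(dtype=float), y, seed)
    ranking = [X.columns[i] for i in ranking_idx]
    selected_idx = sorted(ranking_idx[:n_target])  # keep original column order
    return [X.columns[i] for i in selected_idx], ranking


def choose_rfe_target(X: pd.DataFrame, y, targets=range(3, 11), folds: int = 5,
                      seed: int = 0) -> int:
    """Pick the RFE feature count by cross-validated AUC (ties -> smaller)."""
    X = pd.DataFrame(X)
    y = np.asarray(y)
    targets = [t for t in targets if t <= X.shape[1]]
    if not targets:
        return X.shape[1]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = {t: [] for t in targets}
    Xa = X.to_numpy(dtype=float)
    for tr, va in skf.split(Xa, y):
        ranking = _rfe_ranking(Xa[tr], y[tr], seed)
        for t in targets:
            cols = sorted(ranking[:t])
            est = LogisticRegression(C=1.0, solver="lbfgs",
                                     max_iter=2000, random_state=seed)
            est.fit(Xa[np.ix_(tr, cols)], y[tr])
            s = est.predict_proba(Xa[np.ix_(va, cols)])[:, 1]
            if len(np.unique(y[va])) == 2:
                scores[t].append(roc_auc_score(y[va], s))
    mean_scores = {t: float(np.mean(v)) for t, v in scores.items()}
    return max(sorted(targets), key=lambda t: (mean_scores[t], -t))


# ---------------------------------------------------------------------------
# full chain


@dataclass
class SelectionReport:
    """Survivors and diagnostics of every stage of the selection chain."""

    stages: dict = field(default_factory=dict)   # stage name -> surviving columns
    icc_values: dict = field(default_factory=dict)
    dropped_constant: list = field(default_factory=list)
    lasso_alpha: float | None = None
    rfe_ranking: list = field(default_factory=list)
    rfe_target: int | None = None
    seed: int = 0

    @property
    def selected(self) -> list:
        return list(self.stages.values())[-1] if self.stages else []


def run_selection(train: pd.DataFrame, y_train, *, rater2: pd.DataFrame | None = None,
                  icc_threshold: float = 0.75, pearson_cutoff: float = 0.9,
                  rfe_target: int | None = None, max_missing: float = 0.2,
                  seed: int = 0) -> tuple[SelectionReport, ZScoreNormalizer]:
    """Run the staged selection chain on a training feature table.

    Missing values: columns with more than ``max_missing`` missing entries
    are dropped; the remainder are imputed with the training median before
    normalization.  Returns the report and the fitted normalizer (to be
    applied to test rows with training statistics).
    """
    report = SelectionReport(seed=seed)
    X = train.copy()
    # missingness policy
    frac_missing = X.isna().mean()
    X = X.loc[:, frac_missing <= max_missing]
    X = X.fillna(X.median())
    report.stages["input"] = list(X.columns)

    if rater2 is not None:
        r2 = rater2[X.columns].loc[X.index]
        retained, iccs = icc_filter(X, r2.fillna(r2.median()), icc_threshold)
        report.icc_values = iccs
        X = X[retained]
    report.stages["icc"] = list(X.columns)

    norm = ZScoreNormalizer().fit(X)
    report.dropped_constant = norm.dropped_
    Xn = norm.transform(X)
    report.stages["zscore"] = list(Xn.columns)

    kept = pearson_filter(Xn, cutoff=pearson_cutoff)
    Xn = Xn[kept]
    report.stages["pearson"] = kept

    selected, alpha = lasso_select(Xn, y_train, seed=seed)
    report.lasso_alpha = alpha
    Xn = Xn[selected]
    report.stages["lasso"] = selected

    if rfe_target is None:
        rfe_target = choose_rfe_target(Xn, y_train, seed=seed)
    rfe_target = min(rfe_target, Xn.shape[1])
    final, ranking = rfe_select(Xn, y_train, rfe_target, seed=seed)
    report.rfe_ranking = ranking
    report.rfe_target = rfe_target
    report.stages["rfe"] = final
    return report, norm
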