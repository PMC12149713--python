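"""Outcome-prediction model variants.

Nine variants are supported, mirroring the study design: whole-tumor
radiomics (WH), habitat radiomics (Habitats), conventional MRI features (CF),
immunohistochemistry (IHC), and their combinations (Habitats+CF, CF+IHC,
WH+CF, WH+CF+IHC, Habitats+CF+IHC).  Combined variants concatenate the
selected feature blocks and refit a single classifier rather than stacking
model outputs.  Classifiers are L2 logistic regression (default) or a linear
SVM with Platt-scaled probabilities; performance during development is
summarized by stratified 5-fold cross-validation on the training set.

The CF block defaults to rim enhancement and high T2 signal and the IHC
block to HR negativity and HER2 positivity — the covariate pairs retained by
the univariate screen of the emulated study — but a p < 0.05 univariate
screen is also provided for synthetic covariate tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "VARIANTS",
    "CF_FEATURES",
    "IHC_FEATURES",
    "ModelSpec",
    "PCRClassifier",
    "train_classifier",
    "predict_scores",
    "stratified_cv",
    "univariate_screen",
    "assemble_variant",
]

VARIANTS = ("WH", "Habitats", "CF", "IHC", "Habitats+CF", "CF+IHC",
            "WH+CF", "WH+CF+IHC", "Habitats+CF+IHC")

#: Default conventional-MRI covariates of the CF block.
CF_FEATURES = ("rim_enhancement", "high_t2_signal")
#: Default immunohistochemistry covariates of the IHC block.
IHC_FEATURES = ("hr_negative", "her2_positive")


@dataclass(frozen=True)
class ModelSpec:
    """A model variant, its classifier and hyperparameters."""

    variant: str = "Habitats"
    classifier: str = "logistic"
    C: float = 1.0
    kernel: str = "linear"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.classifier not in ("logistic", "svm"):
            raise ValueError("classifier must be 'logistic' or 'svm'")


class PCRClassifier(BaseEstimator, ClassifierMixin):
    """Binary response classifier behind every model variant.

    A scikit-learn estimator wrapping either L2-penalized logistic
    regression or an SVM with Platt-scaled probabilities; deterministic for
    a given random_state.
    """

    def __init__(self, classifier="logistic", C=1.0, kernel="linear",
                 random_state=0):
        self.classifier = classifier
        self.C = C
        self.kernel = kernel
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("y must contain exactly two classes")
        self.feature_names_ = list(X.columns)
        if self.classifier == "logistic":
            est = LogisticRegression(C=self.C, solver="lbfgs",
                                     max_iter=5000, random_state=self.random_state)
        else:
            # Platt-scaled probabilities, calibrated on training folds
            est = CalibratedClassifierCV(
                SVC(kernel=self.kernel, C=self.C,
                    random_state=self.random_state),
                method="sigmoid", cv=5, ensemble=False)
        est.fit(X.to_numpy(dtype=float), y)
        self.estimator_ = est
        self.classes_ = classes
        return self

    def _check_columns(self, X):
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_:
            raise ValueError("feature columns do not match the training features")
        return X.to_numpy(dtype=float)

    def predict_proba(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.predict_proba(self._check_columns(X))

    def decision_function(self, X):
        check_is_fitted(self, "estimator_")
        return self.estimator_.decision_function(self._check_columns(X))

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class FittedModel:
    """A fitted variant: the estimator, its features and its CV summary."""

    spec: ModelSpec
    classifier: PCRClassifier
    feature_names: list
    cv_auc: list = field(default_factory=list)

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean(self.cv_auc)) if self.cv_auc else np.nan


def stratified_cv(y, folds: int = 5, seed: int = 0) -> np.ndarray:
    """Stratified fold assignment (0..folds-1 per case).

    Every fold's class counts differ from the global ratio by at most one
    case; the assignment is a deterministic function of the seed.
    """
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assign = np.empty(y.shape[0], dtype=int)
    for k, (_, va) in enumerate(skf.split(np.zeros_like(y), y)):
        assign[va] = k
    return assign


def train_classifier(X: pd.DataFrame, y, spec: ModelSpec,
                     cv_folds: int = 5) -> FittedModel:
    """Fit a variant's classifier and record its stratified-CV AUC."""
    X = pd.DataFrame(X)
    y = np.asarray(y).astype(int)
    if X.isna().to_numpy().any():
        raise ValueError("X contains missing values")
    clf = PCRClassifier(classifier=spec.classifier, C=spec.C,
                        kernel=spec.kernel, random_state=spec.seed)
    cv_auc = []
    if min(np.bincount(y)) >= cv_folds:
        folds = stratified_cv(y, cv_folds, spec.seed)
        for k in range(cv_folds):
            tr, va = folds != k, folds == k
            fold_clf = PCRClassifier(classifier=spec.classifier, C=spec.C,
                                     kernel=spec.kernel, random_state=spec.seed)
            fold_clf.fit(X[tr], y[tr])
            if len(np.unique(y[va])) == 2:
                cv_auc.append(roc_auc_score(y[va], fold_clf.predict_proba(X[va])[:, 1]))
    clf.fit(X, y)
    return FittedModel(spec=spec, classifier=clf,
                       feature_names=list(X.columns), cv_auc=cv_auc)


def predict_scores(model: FittedModel, X: pd.DataFrame) -> np.ndarray:
    """Continuous risk scores (probability of response) for new cases."""
    return model.classifier.predict_proba(X)[:, 1]


def univariate_screen(covariates: pd.DataFrame, y, alpha: float = 0.05) -> list:
    """Keep covariates associated with the outcome at p < alpha.

    Binary columns are screened with the chi-square test, continuous ones
    with the two-sample t-test.
    """
    y = np.asarray(y).astype(int)
    kept = []
    for col in covariates.columns:
        x = covariates[col].to_numpy(dtype=float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            table = np.array([[np.sum((x == 1) & (y == 1)), np.sum((x == 1) & (y == 0))],
                              [np.sum((x == 0) & (y == 1)), np.sum((x == 0) & (y == 0))]])
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                continue
            _, p, _, _ = sps.chi2_contingency(table, correction=False)
        else:
            _, p = sps.ttest_ind(x[y == 1], x[y == 0])
        if p < alpha:
            kept.append(col)
    return kept


def assemble_variant(variant: str, blocks: dict) -> pd.DataFrame:
    """Concatenate the feature blocks a variant requires.

    ``blocks`` maps block names ('WH', 'Habitats', 'CF', 'IHC') to aligned
    DataFrames of already-selected features.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    parts = []
    for name in variant.split("+"):
        if name not in blocks or blocks[name] is None:
            raise ValueError(f"variant {variant!r} needs feature block {name!r}")
        parts.append(blocks[name])
    out = pd.concat(parts, axis=1)
    if out.columns.duplicated().any():
        raise ValueError("duplicate feature names across blocks")
    return out
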