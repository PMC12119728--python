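"""Grade-Predictive-Vector machinery: per-lesion imaging feature tables and
LASSO-based predictive vectors with ROC evaluation.

A GpV is a sparse weighted linear combination of standardised PET and MRI
variables selected by L1-penalised logistic regression with seeded
cross-validation.  Two variable inventories exist: the *static* vector
(GpVs) combines static PET (SUV/TBR) with MRI variables; the *dynamic*
vector (GpVd) adds the tracer-kinetic PET constants (Ki, K1, k2, k3, vb).
A fitted vector serialises to JSON — features, weights, standardisation —
so it can be applied unchanged to unseen lesions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import l1_min_c

__all__ = [
    "STATIC_PET_COLUMNS",
    "DYNAMIC_PET_COLUMNS",
    "MRI_COLUMNS",
    "variant_columns",
    "FeatureTable",
    "assemble_features",
    "GpvModelSpec",
    "GpvClassifier",
    "fit_lasso_classifier",
    "compute_gpv",
    "evaluate_classifier",
    "ClassifierEvaluation",
]

STATIC_PET_COLUMNS = ["SUVmax", "SUVmean", "TBRmax", "TBRmean"]
DYNAMIC_PET_COLUMNS = ["Ki_std", "Ki_mod", "K1", "k2", "k3", "vb"]
MRI_COLUMNS = [
    "Ktrans", "Kep", "Ve", "Vp", "Taui",
    "CBF", "CBV", "CBVlc", "MTT", "TTP",
    "ASL_CBF", "ADC",
]


def variant_columns(variant: str) -> list:
    """Column inventory for a vector variant.

    GpVs excludes the dynamic-PET kinetic constants; GpVd and GpV-IMD use
    the full inventory.
    """
    if variant == "GpVs":
        return STATIC_PET_COLUMNS + MRI_COLUMNS
    if variant in ("GpVd", "GpV-IMD"):
        return STATIC_PET_COLUMNS + DYNAMIC_PET_COLUMNS + MRI_COLUMNS
    raise ValueError(f"unknown variant {variant!r}")


@dataclass
class FeatureTable:
    """Standardised lesions x variables matrix with its stored transform."""

    values: pd.DataFrame          # standardised
    mean: pd.Series
    sd: pd.Series
    mask_context: str = "T1"
    variant: str = "GpVd"

    def inverse(self) -> pd.DataFrame:
        return self.values * self.sd + self.mean

    def project(self, raw: pd.DataFrame) -> pd.DataFrame:
        """Apply the stored standardisation to new lesions."""
        missing = [c for c in self.values.columns if c not in raw.columns]
        if missing:
            raise KeyError(f"missing required columns: {missing}")
        return (raw[self.values.columns] - self.mean) / self.sd


def assemble_features(raw: pd.DataFrame, mask_context: str = "T1",
                      variant: str = "GpVd") -> FeatureTable:
    """Standardise the per-lesion quantification outputs for a variant.

    Missing required columns raise with the full gap listed; missing
    values are refused (imputation, if wanted, is the caller's explicit
    decision).
    """
    cols = [c for c in variant_columns(variant) if c in raw.columns]
    missing = [c for c in variant_columns(variant) if c not in raw.columns]
    if missing:
        raise KeyError(f"feature table missing required columns: {missing}")
    sub = raw[cols]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}; impute explicitly first")
    mean = sub.mean()
    sd = sub.std(ddof=0).replace(0.0, 1.0)
    return FeatureTable((sub - mean) / sd, mean, sd, mask_context, variant)


@dataclass
class GpvModelSpec:
    """Serialised form of a fitted predictive vector."""

    variant: str
    features: list
    weights: list               # on the standardised scale, selected features only
    intercept: float
    lam: float
    mean: dict
    sd: dict
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = json.dumps(self.__dict__, indent=1)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "GpvModelSpec":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


class GpvClassifier(BaseEstimator, ClassifierMixin):
    """L1-penalised logistic regression over a seeded CV lambda grid.

    The grid spans 4 decades below lambda_max (the smallest penalty at
    which every weight is zero); lambda is chosen at minimum mean
    cross-validated binomial deviance (``selection='min'``) or by the
    one-standard-error rule (``'1se'``).  Standardisation is internal and
    stored, so ``decision_function`` accepts raw-scale features.
    """

    def __init__(self, n_lambdas: int = 60, n_folds: int = 10,
                 selection: str = "min", random_state: int = 0):
        self.n_lambdas = n_lambdas
        self.n_folds = n_folds
        self.selection = selection
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.feature_names_ = [str(c) for c in X.columns]
        y = np.asarray(y, dtype=int)
        if np.unique(y).size < 2:
            raise ValueError("labels contain a single class")
        self.classes_ = np.unique(y)
        self.mean_ = X.mean()
        self.sd_ = X.std(ddof=0).replace(0.0, 1.0)
        xs = ((X - self.mean_) / self.sd_).to_numpy()
        n = xs.shape[0]

        c_min = l1_min_c(xs, y, loss="log")         # all-zero boundary
        cs = c_min * np.logspace(0.0, 4.0, self.n_lambdas)
        self.lambda_grid_ = 1.0 / (n * cs)          # decreasing penalty order

        def make_clf(c):
            return LogisticRegression(l1_ratio=1.0, C=c, solver="liblinear",
                                      max_iter=5000, tol=1e-8)

        # full-data path (sparsity trace)
        self.path_nnz_ = np.array([
            int(np.sum(np.abs(make_clf(c).fit(xs, y).coef_) > 1e-10)) for c in cs
        ])

        folds = StratifiedKFold(self.n_folds, shuffle=True,
                                random_state=self.random_state)
        dev = np.zeros((self.n_folds, cs.size))
        eps = 1e-12
        for k, (tr, te) in enumerate(folds.split(xs, y)):
            for j, c in enumerate(cs):
                p = make_clf(c).fit(xs[tr], y[tr]).predict_proba(xs[te])[:, 1]
                p = np.clip(p, eps, 1 - eps)
                dev[k, j] = -2.0 * np.mean(y[te] * np.log(p) + (1 - y[te]) * np.log(1 - p))
        self.cv_deviance_ = dev.mean(axis=0)
        self.cv_deviance_se_ = dev.std(axis=0, ddof=1) / np.sqrt(self.n_folds)

        j_min = int(np.argmin(self.cv_deviance_))
        if self.selection == "1se":
            bound = self.cv_deviance_[j_min] + self.cv_deviance_se_[j_min]
            # largest penalty (smallest j, since cs ascend) within one SE
            j_sel = int(np.nonzero(self.cv_deviance_ <= bound)[0][0])
        else:
            j_sel = j_min
        self.lambda_ = float(self.lambda_grid_[j_sel])
        self.C_ = float(cs[j_sel])
        final = make_clf(self.C_).fit(xs, y)
        self.coef_ = final.coef_.ravel()
        self.intercept_ = float(final.intercept_[0])
        self.selected_features_ = [f for f, w in zip(self.feature_names_, self.coef_)
                                   if abs(w) > 1e-10]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = [c for c in self.feature_names_ if c not in X.columns]
        if missing:
            raise KeyError(f"missing features: {missing}")
        xs = ((X[self.feature_names_] - self.mean_) / self.sd_).to_numpy()
        return xs @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    def predict_proba(self, X) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1 - p, p])

    def to_spec(self, variant: str = "GpVd") -> GpvModelSpec:
        sel = self.selected_features_
        weights = [float(w) for f, w in zip(self.feature_names_, self.coef_) if f in sel]
        return GpvModelSpec(
            variant=variant,
            features=sel,
            weights=weights,
            intercept=self.intercept_,
            lam=self.lambda_,
            mean={f: float(self.mean_[f]) for f in sel},
            sd={f: float(self.sd_[f]) for f in sel},
            seed=self.random_state,
        )


def fit_lasso_classifier(table: pd.DataFrame, labels, n_folds: int = 10,
                         seed: int = 0, variant: str = "GpVd",
                         **kwargs) -> GpvModelSpec:
    clf = GpvClassifier(n_folds=n_folds, random_state=seed, **kwargs).fit(table, labels)
    return clf.to_spec(variant=variant)


def compute_gpv(table: pd.DataFrame, spec: GpvModelSpec) -> pd.Series:
    """Score lesions with a (possibly externally supplied) vector.

    Applies the spec's stored standardisation, so a vector trained on one
    cohort transfers unchanged to unseen lesions.
    """
    missing = [f for f in spec.features if f not in table.columns]
    if missing:
        raise KeyError(f"incoming table missing features: {missing}")
    score = np.full(len(table), float(spec.intercept))
    for f, w in zip(spec.features, spec.weights):
        z = (table[f].to_numpy(dtype=float) - spec.mean[f]) / spec.sd[f]
        score = score + w * z
    return pd.Series(score, index=table.index, name=f"{spec.variant}_score")


@dataclass
class ClassifierEvaluation:
    auc: float
    accuracy: float
    threshold: float
    tpr: float
    fpr: float
    roc_fpr: np.ndarray = field(repr=False, default=None)
    roc_tpr: np.ndarray = field(repr=False, default=None)


def evaluate_classifier(scores, labels) -> ClassifierEvaluation:
    """Empirical ROC with trapezoidal AUC and Youden-optimal accuracy."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if np.unique(labels).size < 2:
        raise ValueError("need at least one case per class")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    j = int(np.argmax(tpr - fpr))
    thr = float(thresholds[j])
    pred = scores >= thr
    accuracy = float(np.mean(pred == labels.astype(bool)))
    return ClassifierEvaluation(auc, accuracy, thr, float(tpr[j]), float(fpr[j]),
                                roc_fpr=fpr, roc_tpr=tpr)
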