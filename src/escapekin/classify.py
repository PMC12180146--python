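"""Genotype prediction from the kinematic feature table.

Mutant (-/-) larvae are distinguished from pooled wild-type (+/+ and +/-)
siblings using (a) a random forest with per-tree bootstrap sampling, scored
out-of-bag, and ranked by mean GINI (impurity-decrease) importance; and
(b) a linear soft-margin SVM tuned over C on a stratified 70/30 split with
tenfold cross-validation.  Top-predictor intersections across strain x
model combinations identify robust biomarkers, and correlation-matrix PCA
summarizes how much variability the leading components capture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

WILD_TYPE_GENOTYPES = ("+/+", "+/-")


def genotype_to_label(genotypes: pd.Series | np.ndarray) -> np.ndarray:
    """Binary labels: 1 = mutant (-/-), 0 = pooled wild-type (+/+, +/-)."""
    g = np.asarray(genotypes, dtype=object)
    labels = np.where(g == "-/-", 1, np.where(np.isin(g, WILD_TYPE_GENOTYPES), 0, -1))
    if (labels == -1).any():
        raise ValueError("unknown genotype in label column")
    return labels.astype(int)


@dataclass
class ClassifierReport:
    model: str
    auroc: float
    confusion: np.ndarray          # rows true, cols predicted; [[tn, fp], [fn, tp]]
    error_rate: float
    importance: pd.Series          # per-feature, descending
    cv_accuracies: np.ndarray
    seed: int
    params: dict = field(default_factory=dict)

    def top_features(self, k: int = 6) -> list[str]:
        return list(self.importance.index[:k])

    def as_dict(self) -> dict:
        return {
            "model": self.model,
            "auroc": self.auroc,
            "confusion": self.confusion.tolist(),
            "error_rate": self.error_rate,
            "importance": self.importance.to_dict(),
            "cv_accuracies": self.cv_accuracies.tolist(),
            "seed": self.seed,
            "params": self.params,
        }


def _rank(importance: np.ndarray, names: list[str]) -> pd.Series:
    """Importance ranking with deterministic ties broken by catalog order."""
    order = np.lexsort((np.arange(len(names)), -importance))
    return pd.Series(importance[order], index=[names[i] for i in order])


def fit_random_forest(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    n_estimators: int = 500,
) -> ClassifierReport:
    """Random forest scored out-of-bag.

    Each tree trains on a bootstrap sample (leaving ~1/3 of larvae
    out-of-bag); the OOB votes give the error rate, confusion matrix and
    AUROC.  Importance is the mean GINI (impurity) decrease per feature.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit a classifier")
    rf = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small cohorts: some rows never OOB
        rf.fit(X, y)
    oob_prob = rf.oob_decision_function_[:, 1]
    valid = np.isfinite(oob_prob)
    pred = (oob_prob[valid] >= 0.5).astype(int)
    conf = confusion_matrix(y[valid], pred, labels=[0, 1])
    n_splits = min(10, int(np.bincount(y).min()))
    cv = cross_val_score(
        rf, X, y,
        cv=StratifiedKFold(max(2, n_splits), shuffle=True, random_state=seed),
        scoring="accuracy", n_jobs=1,
    )
    return ClassifierReport(
        model="random_forest",
        auroc=float(roc_auc_score(y[valid], oob_prob[valid])),
        confusion=conf,
        error_rate=float(np.mean(pred != y[valid])),
        importance=_rank(rf.feature_importances_, list(features.columns)),
        cv_accuracies=cv,
        seed=seed,
        params={"n_estimators": n_estimators, "max_features": "sqrt"},
    )


def fit_linear_svm(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    c_grid: np.ndarray | None = None,
    test_fraction: float = 0.30,
) -> ClassifierReport:
    """Linear SVM with C tuned by tenfold CV on a stratified 70/30 split.

    Features are z-scored on the training split.  C ranges over (0.01, 5]
    (50 log-spaced values by default; C = 0 yields no margin penalty and is
    ill-posed, so the grid starts just above zero).  The confusion matrix
    and error rate come from the held-out 30%; AUROC from its decision
    values; importance is |weight| per feature.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes to fit a classifier")
    if c_grid is None:
        c_grid = np.logspace(np.log10(0.01), np.log10(5.0), 50)

    Xtr, Xte, ytr, yte = train_test_split(
        X, y, test_size=test_fraction, stratify=y, random_state=seed
    )
    if len(np.unique(yte)) < 2:  # pragma: no cover - stratify prevents this
        warnings.warn("test split missing a class; re-splitting", stacklevel=2)
        Xtr, Xte, ytr, yte = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=seed + 1
        )

    def make(c: float) -> Pipeline:
        return Pipeline([
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=c, random_state=seed)),
        ])

    n_splits = min(10, int(np.bincount(ytr).min()))
    cv = StratifiedKFold(n_splits, shuffle=True, random_state=seed)
    scores = {
        float(c): cross_val_score(make(c), Xtr, ytr, cv=cv, n_jobs=1).mean()
        for c in c_grid
    }
    best_c = max(scores, key=lambda c: (scores[c], -c))
    model = make(best_c).fit(Xtr, ytr)
    dec = model.decision_function(Xte)
    pred = model.predict(Xte)
    conf = confusion_matrix(yte, pred, labels=[0, 1])
    weights = np.abs(model.named_steps["svm"].coef_.ravel())
    cv_acc = cross_val_score(make(best_c), Xtr, ytr, cv=cv, n_jobs=1)
    return ClassifierReport(
        model="linear_svm",
        auroc=float(roc_auc_score(yte, dec)),
        confusion=conf,
        error_rate=float(np.mean(pred != yte)),
        importance=_rank(weights, list(features.columns)),
        cv_accuracies=cv_acc,
        seed=seed,
        params={"C": best_c, "cv_folds": n_splits, "test_fraction": test_fraction},
    )


@dataclass
class PredictorIntersection:
    top_k: dict[str, list[str]]    # per (strain x model) label
    intersection: list[str]
    k: int


def top_predictor_intersection(
    reports: dict[str, ClassifierReport], k: int = 6
) -> PredictorIntersection:
    """Features common to every report's top-k importance list.

    Reports are keyed by a strain x model label (four in the canonical
    design).  The intersection is ordered by feature-catalog position of the
    first report for determinism.
    """
    tops = {label: rep.top_features(k) for label, rep in reports.items()}
    sets = [set(t) for t in tops.values()]
    common = set.intersection(*sets) if sets else set()
    first = next(iter(tops.values())) if tops else []
    ordered = [f for f in first if f in common]
    return PredictorIntersection(top_k=tops, intersection=ordered, k=k)


@dataclass
class PCAVariance:
    explained: np.ndarray          # per-component fraction
    cumulative: np.ndarray
    dropped: list[str]

    @property
    def first_two(self) -> float:
        return float(self.cumulative[min(1, len(self.cumulative) - 1)])


def pca_variance(
    features: pd.DataFrame, variable_subset: list[str] | None = None
) -> PCAVariance:
    """Explained-variance fractions of correlation-matrix PCA.

    Variables are centered and unit-scaled (constant columns dropped with a
    warning), so components are eigenvectors of the correlation matrix and
    the fractions sum to 1.
    """
    df = features[variable_subset] if variable_subset is not None else features
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 variables for PCA")
    sd = X.std(axis=0, ddof=1)
    dropped = [c for c, s in zip(df.columns, sd) if s == 0]
    if dropped:
        warnings.warn(f"dropped constant variables: {dropped}", stacklevel=2)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    # eigenvalues of the correlation matrix via SVD of the z-scored data
    svals = np.linalg.svd(Z, compute_uv=False)
    ev = svals**2
    explained = ev / ev.sum()
    return PCAVariance(
        explained=explained,
        cumulative=np.cumsum(explained),
        dropped=dropped,
    )
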