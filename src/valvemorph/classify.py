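"""Species classification experiments: three feature sets (non-EFD, EFD,
both) crossed with five algorithms (naive Bayes, LDA, QDA, SVM, random
forest), evaluated by resubstitution and by replicated 10-fold
cross-validation. Class labels are majority-vote species; ambiguous or tied
specimens are excluded before classification, and specimens with any
missing value in the chosen feature set are dropped (complete cases)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import SPECIES
from .outline import NON_EFD_FEATURES, efd_columns

__all__ = [
    "FeatureSetSpec",
    "ClassifierReport",
    "CVReport",
    "ALGORITHMS",
    "build_feature_sets",
    "classification_labels",
    "make_classifier",
    "fit_predict_resubstitution",
    "cross_validate",
]

ALGORITHMS = ("naive_bayes", "lda", "qda", "svm", "random_forest")


@dataclass
class FeatureSetSpec:
    name: str  # non_EFD | EFD | both
    variables: list[str]


@dataclass
class ClassifierReport:
    algorithm: str
    feature_set: str
    n_cases: int
    misclassified: int | None
    misclassified_pct: float | None
    not_applicable: bool = False
    reason: str = ""


@dataclass
class CVReport:
    algorithm: str
    feature_set: str
    replicates: int
    per_replicate_pct: np.ndarray = field(repr=False)
    mean_pct: float = 0.0
    min_pct: float = 0.0
    max_pct: float = 0.0


def build_feature_sets(
    features: pd.DataFrame, n_harmonics: int = 14
) -> dict[str, tuple[FeatureSetSpec, pd.DataFrame]]:
    """Assemble the three feature sets and their complete-case matrices.

    non_EFD: the 19 scalar morphometric variables; EFD: the 4 x n_harmonics
    Fourier coefficients (56 for the default 14 harmonics); both: the union.
    Specimens with any missing value in a set are dropped from that set only.
    """
    efd_vars = efd_columns(n_harmonics)
    sets = {
        "non_EFD": list(NON_EFD_FEATURES),
        "EFD": efd_vars,
        "both": list(NON_EFD_FEATURES) + efd_vars,
    }
    out = {}
    for name, variables in sets.items():
        missing_cols = [v for v in variables if v not in features.columns]
        if missing_cols:
            raise KeyError(f"feature set {name}: absent variables {missing_cols}")
        mat = features.set_index("specimen_id")[variables].dropna()
        out[name] = (FeatureSetSpec(name, variables), mat)
    return out


def classification_labels(consensus: pd.DataFrame) -> pd.Series:
    """Majority-vote species labels; ambiguous/tied specimens excluded."""
    cons = consensus.set_index("specimen_id") if "specimen_id" in consensus else consensus
    keep = cons["majority_label"].isin(SPECIES) & ~cons["tie"].astype(bool)
    return cons.loc[keep, "majority_label"]


def make_classifier(algorithm: str, seed: int | None = None):
    """Classifier with the study's settings: SVM is an RBF kernel with cost 1
    and kernel width 1/p on standardized variables; the random forest has 500
    trees with sqrt(p) candidate variables per split; naive Bayes uses
    per-class univariate normals."""
    if algorithm == "naive_bayes":
        return GaussianNB()
    if algorithm == "lda":
        return LinearDiscriminantAnalysis()
    if algorithm == "qda":
        return QuadraticDiscriminantAnalysis()
    if algorithm == "svm":
        return make_pipeline(StandardScaler(), SVC(C=1.0, kernel="rbf", gamma="auto"))
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=500, max_features="sqrt", random_state=seed
        )
    raise ValueError(f"unknown algorithm {algorithm!r}")


def _aligned(matrix: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series]:
    ids = matrix.index.intersection(labels.index)
    return matrix.loc[ids], labels.loc[ids]


def fit_predict_resubstitution(
    matrix: pd.DataFrame,
    labels: pd.Series,
    algorithm: str,
    feature_set: str = "",
    seed: int | None = 0,
) -> ClassifierReport:
    """Fit on all cases and predict the same cases.

    QDA needs a nonsingular per-class covariance, so it is reported as not
    applicable whenever some class has no more cases than variables.
    """
    X, y = _aligned(matrix, labels)
    n, p = X.shape
    if y.nunique() < 2:
        raise ValueError("need >= 2 classes")
    if algorithm == "qda":
        class_counts = y.value_counts()
        if (class_counts <= p).any():
            small = class_counts[class_counts <= p]
            return ClassifierReport(
                algorithm, feature_set, n, None, None, True,
                reason=(
                    "singular class covariance: class n <= p for "
                    + ", ".join(f"{k} ({v} cases, {p} variables)" for k, v in small.items())
                ),
            )
    clf = make_classifier(algorithm, seed)
    clf.fit(X.to_numpy(), y.to_numpy())
    pred = clf.predict(X.to_numpy())
    mis = int(np.sum(pred != y.to_numpy()))
    return ClassifierReport(algorithm, feature_set, n, mis, 100.0 * mis / n)


def cross_validate(
    matrix: pd.DataFrame,
    labels: pd.Series,
    algorithm: str,
    folds: int = 10,
    replicates: int = 1000,
    seed: int = 0,
    feature_set: str = "",
    stratified: bool = False,
    max_refolds: int = 20,
) -> CVReport:
    """Replicated k-fold cross-validation; per replicate a fresh random fold
    partition (unstratified by default), pooled test misclassification %.

    Discriminant classifiers need every class in every training fold; a
    partition violating this is redrawn up to ``max_refolds`` times.
    """
    X, y = _aligned(matrix, labels)
    n = len(X)
    if n < folds:
        raise ValueError(f"n_cases={n} < folds={folds}")
    rng = np.random.default_rng(seed)
    Xa, ya = X.to_numpy(), y.to_numpy()
    classes = np.unique(ya)
    errors = np.empty(replicates)
    for rep in range(replicates):
        for _attempt in range(max_refolds):
            if stratified:
                fold_of = np.empty(n, dtype=int)
                for c in classes:
                    idx = np.flatnonzero(ya == c)
                    rng.shuffle(idx)
                    fold_of[idx] = np.arange(len(idx)) % folds
            else:
                perm = rng.permutation(n)
                fold_of = np.empty(n, dtype=int)
                fold_of[perm] = np.arange(n) % folds
            ok = all(
                len(np.unique(ya[fold_of != f])) == len(classes) for f in range(folds)
            )
            if ok or algorithm not in ("lda", "qda"):
                break
        else:
            return CVReport(algorithm, feature_set, 0, np.array([]), np.nan, np.nan, np.nan)
        wrong = 0
        for f in range(folds):
            test = fold_of == f
            clf = make_classifier(algorithm, int(rng.integers(2**31)))
            clf.fit(Xa[~test], ya[~test])
            wrong += int(np.sum(clf.predict(Xa[test]) != ya[test]))
        errors[rep] = 100.0 * wrong / n
    return CVReport(
        algorithm=algorithm,
        feature_set=feature_set,
        replicates=replicates,
        per_replicate_pct=errors,
        mean_pct=float(errors.mean()),
        min_pct=float(errors.min()),
        max_pct=float(errors.max()),
    )
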