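"""Wrapper classifiers.

The k-nearest-neighbour classifier (six distances, three weighting
rules, optional training-set standardization) and the random-subspace
linear-discriminant ensemble are implemented here in full, since they
carry the headline results.  The remaining preset classifiers (trees,
discriminants, logistic regression, naive Bayes, SVMs) are thin
adapters over scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .table import LabeledTable

__all__ = [
    "KNNSpec",
    "SubspaceEnsembleSpec",
    "PresetSpec",
    "knn_predict",
    "subspace_discriminant_predict",
    "predict",
    "PRESET_NAMES",
]

KNN_DISTANCES = (
    "euclidean", "cityblock", "cosine", "correlation", "spearman", "hamming",
)
KNN_WEIGHTS = ("equal", "inverse", "squared_inverse")


@dataclass(frozen=True)
class KNNSpec:
    """k-nearest-neighbour configuration."""

    n_neighbors: int = 10
    distance: str = "euclidean"
    weighting: str = "equal"
    standardize: bool = False

    def __post_init__(self):
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be >= 1")
        if self.distance not in KNN_DISTANCES:
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.weighting not in KNN_WEIGHTS:
            raise ValueError(f"unknown weighting {self.weighting!r}")


@dataclass(frozen=True)
class SubspaceEnsembleSpec:
    """Random-subspace ensemble of linear discriminants."""

    n_learners: int = 30
    subspace_dim: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.n_learners < 1:
            raise ValueError("n_learners must be >= 1")
        if self.subspace_dim < 1:
            raise ValueError("subspace_dim must be >= 1")


@dataclass(frozen=True)
class PresetSpec:
    """A named scikit-learn-backed preset classifier."""

    name: str
    params: tuple = field(default=())  # extra (key, value) overrides

    def __post_init__(self):
        if self.name not in PRESET_NAMES:
            raise ValueError(f"unknown preset {self.name!r}; know {PRESET_NAMES}")


# ----------------------------------------------------------------------
# kNN
# ----------------------------------------------------------------------

def _as_arrays(train, test):
    if isinstance(train, LabeledTable):
        X_train, y_train = train.to_matrix(), np.asarray(train.y)
    else:
        X_train, y_train = train
        X_train = np.asarray(X_train, dtype=float)
        y_train = np.asarray(y_train)
    if isinstance(test, LabeledTable):
        X_test = test.to_matrix()
    else:
        X_test = np.asarray(test, dtype=float)
    if X_test.ndim == 1:
        X_test = X_test[None, :]
    return X_train, y_train, X_test


def _standardize(X_train, X_test):
    mu = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"ignoring {int((~keep).sum())} zero-variance column(s) during "
            "standardization",
            stacklevel=3,
        )
    return (X_train[:, keep] - mu[keep]) / sd[keep], (X_test[:, keep] - mu[keep]) / sd[keep]


def _distances(X_test, X_train, metric):
    if metric == "spearman":
        # Spearman distance = correlation distance on within-row ranks
        X_test = rankdata(X_test, axis=1)
        X_train = rankdata(X_train, axis=1)
        metric = "correlation"
    with np.errstate(divide="ignore", invalid="ignore"):
        d = cdist(X_test, X_train, metric=metric)
    # constant rows make correlation-type distances undefined; treat as
    # maximally dissimilar
    return np.nan_to_num(d, nan=1.0)


def _majority_label(y_train):
    labels, counts = np.unique(y_train, return_counts=True)
    return labels[np.argmax(counts)]  # ties -> smallest label (unique is sorted)


def knn_predict(train, test, spec: KNNSpec) -> np.ndarray:
    """Predict labels for ``test`` rows by weighted k-nearest-neighbour vote.

    ``train`` is a :class:`LabeledTable` or an ``(X, y)`` pair; ``test``
    a table or row matrix.  Exact matches (distance 0) dominate the
    inverse and squared-inverse weightings.  Vote ties fall back to the
    training majority class.
    """
    X_train, y_train, X_test = _as_arrays(train, test)
    if X_train.shape[0] == 0:
        raise ValueError("empty training set")
    k = spec.n_neighbors
    if k > X_train.shape[0]:
        raise ValueError(f"n_neighbors={k} exceeds training size {X_train.shape[0]}")
    if spec.standardize:
        X_train, X_test = _standardize(X_train, X_test)

    d = _distances(X_test, X_train, spec.distance)
    # stable sort keeps earlier training rows at equal distance
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(d, order, axis=1)
    lab = y_train[order]

    if spec.weighting == "equal":
        w = np.ones_like(dist)
    else:
        with np.errstate(divide="ignore"):
            w = 1.0 / dist if spec.weighting == "inverse" else 1.0 / dist**2
        # exact matches dominate: rows with any zero distance vote among
        # those matches only
        exact = dist == 0
        exact_rows = exact.any(axis=1)
        w[exact_rows] = exact[exact_rows].astype(float)

    classes = np.unique(y_train)
    votes = np.stack([(w * (lab == c)).sum(axis=1) for c in classes], axis=1)
    best = votes.max(axis=1, keepdims=True)
    tied = (votes == best).sum(axis=1) > 1
    out = classes[np.argmax(votes, axis=1)]
    out[tied] = _majority_label(y_train)  # vote ties -> training majority
    return out


# ----------------------------------------------------------------------
# random-subspace discriminant ensemble
# ----------------------------------------------------------------------

def subspace_discriminant_predict(train, test, spec: SubspaceEnsembleSpec) -> np.ndarray:
    """Average linear-discriminant posteriors over random feature subsets."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    X_train, y_train, X_test = _as_arrays(train, test)
    n_features = X_train.shape[1]
    if spec.subspace_dim > n_features:
        raise ValueError(
            f"subspace_dim={spec.subspace_dim} exceeds feature count {n_features}"
        )
    rng = np.random.default_rng(spec.seed)
    classes = np.unique(y_train)
    score = np.zeros((X_test.shape[0], classes.size))
    for _ in range(spec.n_learners):
        cols = rng.choice(n_features, size=spec.subspace_dim, replace=False)
        lda = LinearDiscriminantAnalysis()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # collinear subspaces are expected
            lda.fit(X_train[:, cols], y_train)
            proba = lda.predict_proba(X_test[:, cols])
        # align learner's class order with the global one
        idx = np.searchsorted(lda.classes_, classes)
        score += proba[:, idx]
    return classes[np.argmax(score, axis=1)]


# ----------------------------------------------------------------------
# scikit-learn preset adapters
# ----------------------------------------------------------------------

def _make_preset(name, overrides):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    factories = {
        # trees: split budget of 100, Gini criterion
        "DT": lambda: DecisionTreeClassifier(max_leaf_nodes=101, random_state=0),
        "FDT": lambda: DecisionTreeClassifier(max_leaf_nodes=101, random_state=0),
        "CDT": lambda: DecisionTreeClassifier(max_leaf_nodes=5, random_state=0),
        "LDA": lambda: LinearDiscriminantAnalysis(),
        "LR": lambda: LogisticRegression(max_iter=2000),
        "NB": lambda: GaussianNB(),
        "GNB": lambda: GaussianNB(),
        "LSVM": lambda: make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0)),
        "MGSVM": lambda: make_pipeline(
            StandardScaler(), SVC(kernel="rbf", gamma=1.0 / (5.6**2), C=1.0)
        ),
        "CGSVM": lambda: make_pipeline(
            StandardScaler(), SVC(kernel="rbf", gamma=1.0 / (22.0**2), C=1.0)
        ),
        "SVM": lambda: make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0)),
    }
    est = factories[name]()
    if overrides:
        est.set_params(**dict(overrides))
    return est


PRESET_NAMES = (
    "DT", "FDT", "CDT", "LDA", "LR", "NB", "GNB", "LSVM", "MGSVM", "CGSVM", "SVM",
)


def predict(spec, train, test) -> np.ndarray:
    """Dispatch on the spec type and return predicted labels for ``test``."""
    if isinstance(spec, KNNSpec):
        return knn_predict(train, test, spec)
    if isinstance(spec, SubspaceEnsembleSpec):
        return subspace_discriminant_predict(train, test, spec)
    if isinstance(spec, PresetSpec):
        X_train, y_train, X_test = _as_arrays(train, test)
        est = _make_preset(spec.name, spec.params)
        est.fit(X_train, y_train)
        return est.predict(X_test)
    raise TypeError(f"unknown classifier spec {type(spec).__name__}")
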