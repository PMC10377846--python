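"""K-fold evaluation and hyperparameter search.

Out-of-fold predictions are pooled into a single confusion matrix
(micro aggregation) before computing metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from . import preprocessing
from .classifiers import KNNSpec, predict
from .metrics import MetricsReport, confusion_metrics
from .table import LabeledTable

__all__ = [
    "CVConfig",
    "make_folds",
    "cross_val_predictions",
    "cross_validate",
    "error_rate",
    "tune_knn",
    "DEFAULT_KNN_GRID",
]


@dataclass(frozen=True)
class CVConfig:
    """K-fold split configuration (stratified by default)."""

    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("K must be >= 2")


def make_folds(y, cv: CVConfig) -> list:
    """Seeded (train_idx, test_idx) splits covering every row once."""
    from sklearn.model_selection import KFold, StratifiedKFold

    y = np.asarray(y)
    if cv.stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < cv.k:
            raise ValueError(
                f"stratified {cv.k}-fold needs >= {cv.k} members per class, "
                f"smallest class has {counts.min()}"
            )
        splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    else:
        splitter = KFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros_like(y), y)]


def cross_val_predictions(X, y, spec, folds) -> np.ndarray:
    """Out-of-fold predictions over precomputed folds."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    out = np.empty_like(y)
    for train_idx, test_idx in folds:
        if np.unique(y[train_idx]).size < 2:
            warnings.warn("training fold contains a single class", stacklevel=2)
        out[test_idx] = predict(spec, (X[train_idx], y[train_idx]), X[test_idx])
    return out


def error_rate(X, y, spec, folds) -> float:
    """Pooled cross-validated misclassification rate."""
    pred = cross_val_predictions(X, y, spec, folds)
    return float(np.mean(pred != np.asarray(y)))


def _fold_tables(table, train_idx, test_idx):
    train = table.select_rows(train_idx)
    test = table.select_rows(test_idx)
    imp = preprocessing.fit_imputer(train)
    train = preprocessing.apply_imputer(train, imp)
    test = preprocessing.apply_imputer(test, imp)
    norm = preprocessing.fit_normalizer(train)
    train = preprocessing.apply_normalizer(train, norm)
    test = preprocessing.apply_normalizer(test, norm)
    return train, test


def cross_validate(table: LabeledTable, spec, cv: CVConfig,
                   positive_label: int = 1,
                   fit_preprocess_per_fold: bool = False) -> MetricsReport:
    """K-fold cross-validation with a pooled confusion matrix.

    With ``fit_preprocess_per_fold`` the imputer and normalizer are
    refit on each training fold (leakage-free mode); otherwise the
    table is used as given.
    """
    y = np.asarray(table.y)
    if np.unique(y).size < 2:
        raise ValueError("table must contain both classes")
    folds = make_folds(y, cv)
    if fit_preprocess_per_fold:
        pred = np.empty_like(y)
        for train_idx, test_idx in folds:
            tr, te = _fold_tables(table, train_idx, test_idx)
            pred[test_idx] = predict(spec, tr, te)
    else:
        pred = cross_val_predictions(table.to_matrix(), y, spec, folds)

    pos = positive_label
    tp = int(np.sum((pred == pos) & (y == pos)))
    fp = int(np.sum((pred == pos) & (y != pos)))
    tn = int(np.sum((pred != pos) & (y != pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    return confusion_metrics(tp, fp, tn, fn)


# ----------------------------------------------------------------------
# hyperparameter search for kNN
# ----------------------------------------------------------------------

DEFAULT_KNN_GRID = {
    "n_neighbors": [1, 2, 4, 8, 16, 32],
    "distance": list(("euclidean", "cityblock", "cosine", "correlation",
                      "spearman", "hamming")),
    "weighting": ["equal", "inverse", "squared_inverse"],
    "standardize": [False, True],
}


def tune_knn(table: LabeledTable, search_space: dict = None, budget: int = None,
             cv: CVConfig = CVConfig(), seed: int = 0) -> KNNSpec:
    """Pick the kNN configuration with the best cross-validated accuracy.

    Evaluates the full grid when ``budget`` covers it, otherwise a
    seeded random sample of ``budget`` configurations.  All candidates
    share the same folds.  Accuracy ties go to fewer neighbours, then
    to grid order.
    """
    space = search_space or DEFAULT_KNN_GRID
    keys = list(space)
    if any(len(space[k]) == 0 for k in keys):
        raise ValueError("empty search space")
    grid = [dict(zip(keys, combo)) for combo in itertools.product(*(space[k] for k in keys))]
    if budget is not None:
        if budget < 1:
            raise ValueError("budget must be >= 1")
        if budget < len(grid):
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(grid), size=budget, replace=False)
            grid = [grid[i] for i in sorted(idx)]

    y = np.asarray(table.y)
    X = table.to_matrix()
    folds = make_folds(y, cv)
    max_k = min(len(tr) for tr, _ in folds)

    best = None
    for params in grid:
        spec = KNNSpec(**params)
        if spec.n_neighbors > max_k:
            continue
        err = error_rate(X, y, spec, folds)
        key = (err, spec.n_neighbors)
        if best is None or key < best[0]:
            best = (key, spec)
    if best is None:
        raise ValueError("no feasible configuration in the search space")
    return best[1]
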