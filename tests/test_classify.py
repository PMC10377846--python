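import numpy as np
import pandas as pd
import pytest

from osadx.classifiers import (
    KNNSpec,
    PresetSpec,
    SubspaceEnsembleSpec,
    knn_predict,
    predict,
    subspace_discriminant_predict,
)
from osadx.evaluation import (
    CVConfig,
    cross_validate,
    make_folds,
    tune_knn,
)
from osadx.metrics import (
    balanced_auc,
    confusion_metrics,
    f_score,
    g_mean,
    mean_rank,
    roc_auc,
    wilcoxon_signed_rank,
)
from osadx.table import NUMERIC, LabeledTable


def numeric_table(X, y):
    frame = pd.DataFrame(np.asarray(X, dtype=float))
    frame.columns = [f"x{i}" for i in range(frame.shape[1])]
    return LabeledTable(frame, np.asarray(y), (NUMERIC,) * frame.shape[1])


# ----------------------------------------------------------------------
# kNN
# ----------------------------------------------------------------------

class TestKNN:
    def test_single_training_row(self):
        pred = knn_predict(([[0.0, 0.0]], [1]), [[5.0, 5.0], [-1.0, 2.0]],
                           KNNSpec(n_neighbors=1))
        assert list(pred) == [1, 1]

    def test_exact_match_dominates(self):
        train = ([[0.0], [1.0], [2.0]], [0, 1, 0])
        pred = knn_predict(train, [[1.0]], KNNSpec(n_neighbors=1))
        assert pred[0] == 1

    def test_squared_inverse_weighting(self):
        # neighbors at d=1 (label 1) and d=2 (label 0): weights 1 vs 0.25
        train = ([[1.0], [-2.0]], [1, 0])
        pred = knn_predict(train, [[0.0]],
                           KNNSpec(n_neighbors=2, weighting="squared_inverse"))
        assert pred[0] == 1
        # equal weighting at k=2 ties -> majority of train = either; with
        # balanced train the tie falls back to the smaller label
        pred_eq = knn_predict(train, [[0.0]], KNNSpec(n_neighbors=2))
        assert pred_eq[0] == 0

    def test_k_exceeds_train_size(self):
        with pytest.raises(ValueError, match="exceeds"):
            knn_predict(([[0.0]], [0]), [[1.0]], KNNSpec(n_neighbors=2))

    def test_self_prediction_perfect_when_distinct(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 4))
        y = rng.integers(0, 2, 30)
        pred = knn_predict((X, y), X, KNNSpec(n_neighbors=1))
        assert np.array_equal(pred, y)

    def test_zero_variance_column_warns_under_standardize(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            knn_predict((X, [0, 1, 0]), X, KNNSpec(n_neighbors=1, standardize=True))

    @pytest.mark.parametrize(
        "distance",
        ["euclidean", "cityblock", "cosine", "correlation", "spearman", "hamming"],
    )
    def test_all_distances_run(self, distance):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 5))
        y = (X[:, 0] > 0).astype(int)
        pred = knn_predict((X, y), X[:5], KNNSpec(n_neighbors=3, distance=distance))
        assert pred.shape == (5,)
        assert set(pred) <= {0, 1}

    def test_spearman_is_rank_invariant(self):
        # monotone transforms of a test row do not change Spearman distances
        rng = np.random.default_rng(4)
        X = rng.normal(size=(25, 6))
        y = rng.integers(0, 2, 25)
        spec = KNNSpec(n_neighbors=3, distance="spearman")
        row = rng.normal(size=(1, 6))
        assert knn_predict((X, y), row, spec)[0] == knn_predict((X, y), row**3, spec)[0]

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            KNNSpec(n_neighbors=0)
        with pytest.raises(ValueError):
            KNNSpec(distance="mahalanobis")
        with pytest.raises(ValueError):
            KNNSpec(weighting="gaussian")


# ----------------------------------------------------------------------
# subspace discriminant ensemble
# ----------------------------------------------------------------------

class TestSubspaceEnsemble:
    def test_degenerate_equals_single_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(0)
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        Xt = rng.normal(size=(20, 4))
        spec = SubspaceEnsembleSpec(n_learners=1, subspace_dim=4, seed=0)
        pred = subspace_discriminant_predict((X, y), Xt, spec)
        lda = LinearDiscriminantAnalysis().fit(X, y)
        assert np.array_equal(pred, lda.predict(Xt))

    def test_separated_classes(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            X = np.vstack(
                [rng.normal(-3, 1, (n, 6)), rng.normal(3, 1, (n, 6))]
            )
            y = np.array([0] * n + [1] * n)
            spec = SubspaceEnsembleSpec(n_learners=10, subspace_dim=3, seed=seed)
            pred = subspace_discriminant_predict((X, y), X, spec)
            assert (pred == y).mean() >= 0.95

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 8))
        y = rng.integers(0, 2, 50)
        spec = SubspaceEnsembleSpec(n_learners=5, subspace_dim=3, seed=7)
        a = subspace_discriminant_predict((X, y), X, spec)
        b = subspace_discriminant_predict((X, y), X, spec)
        assert np.array_equal(a, b)

    def test_subspace_too_large(self):
        X = np.zeros((10, 3))
        with pytest.raises(ValueError, match="exceeds"):
            subspace_discriminant_predict(
                (X, [0, 1] * 5), X, SubspaceEnsembleSpec(subspace_dim=4)
            )


# ----------------------------------------------------------------------
# cross-validation
# ----------------------------------------------------------------------

class TestCrossValidate:
    def test_partition(self):
        y = np.array([0, 1] * 25)
        folds = make_folds(y, CVConfig(k=5, seed=0))
        seen = np.concatenate([te for _, te in folds])
        assert sorted(seen) == list(range(50))

    def test_counts_conserved(self):
        rng = np.random.default_rng(2)
        table = numeric_table(rng.normal(size=(60, 3)), rng.integers(0, 2, 60))
        rep = cross_validate(table, KNNSpec(n_neighbors=3), CVConfig(k=5, seed=1))
        assert rep.total == 60

    def test_perfectly_separable(self):
        X = np.vstack([np.full((25, 2), -10.0), np.full((25, 2), 10.0)])
        X += np.random.default_rng(0).normal(scale=0.01, size=X.shape)
        y = np.array([0] * 25 + [1] * 25)
        rep = cross_validate(numeric_table(X, y), KNNSpec(1), CVConfig(k=5, seed=0))
        assert rep.accuracy == 1.0

    def test_stratified_requires_k_members(self):
        y = np.array([1] * 3 + [0] * 30)
        with pytest.raises(ValueError, match="stratified"):
            make_folds(y, CVConfig(k=5, seed=0))

    def test_single_class_rejected(self):
        table = numeric_table(np.zeros((20, 2)), np.ones(20, dtype=int))
        with pytest.raises(ValueError):
            cross_validate(table, KNNSpec(1), CVConfig(k=5))

    def test_per_fold_preprocessing_handles_missing(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 3))
        X[rng.random(X.shape) < 0.1] = np.nan
        table = numeric_table(X, rng.integers(0, 2, 40))
        rep = cross_validate(
            table, KNNSpec(3), CVConfig(k=4, seed=2), fit_preprocess_per_fold=True
        )
        assert rep.total == 40

    def test_positive_label_swap(self):
        rng = np.random.default_rng(6)
        table = numeric_table(rng.normal(size=(40, 2)), np.array([0, 1] * 20))
        a = cross_validate(table, KNNSpec(3), CVConfig(k=4, seed=3), positive_label=1)
        b = cross_validate(table, KNNSpec(3), CVConfig(k=4, seed=3), positive_label=0)
        assert a.tp == b.tn and a.fp == b.fn
        assert a.accuracy == pytest.approx(b.accuracy)


# ----------------------------------------------------------------------
# metrics
# ----------------------------------------------------------------------

class TestConfusionMetrics:
    def test_reported_auc_identity(self):
        assert balanced_auc(0.8322, 0.6320) == pytest.approx(0.7321, abs=5e-5)

    def test_reported_g_mean(self):
        assert g_mean(0.6316, 0.8939) == pytest.approx(0.7514, abs=5e-5)

    def test_reported_f_score(self):
        assert f_score(0.8372, 0.6316) == pytest.approx(0.7200, abs=5e-5)

    def test_degenerate_all_positive_predictions(self):
        # TPR=1, TNR=0 -> G-mean 0, balanced accuracy 0.5
        rep = confusion_metrics(tp=85, fp=33, tn=0, fn=0)
        assert rep.tpr == 1.0 and rep.tnr == 0.0
        assert rep.g_mean == 0.0
        assert rep.auc == 0.5
        assert "tnr" not in rep.undefined  # denominator fp+tn = 33 > 0

    def test_internal_consistency(self):
        rep = confusion_metrics(tp=36, fp=7, tn=59, fn=21)
        assert rep.accuracy == pytest.approx((36 + 59) / 123)
        assert rep.accuracy == pytest.approx(0.7724, abs=5e-5)
        assert rep.tpr == pytest.approx(36 / 57)
        assert rep.tnr == pytest.approx(59 / 66)
        assert rep.auc == pytest.approx((rep.tpr + rep.tnr) / 2, abs=1e-12)
        assert rep.g_mean == pytest.approx(np.sqrt(rep.tpr * rep.tnr), abs=1e-12)
        assert rep.f_score == pytest.approx(
            2 * rep.precision * rep.tpr / (rep.precision + rep.tpr), abs=1e-12
        )
        # accuracy = class-size-weighted mean of TPR and TNR
        n_pos, n_neg = 57, 66
        assert rep.accuracy == pytest.approx(
            (n_pos * rep.tpr + n_neg * rep.tnr) / (n_pos + n_neg), abs=1e-12
        )

    def test_undefined_flagged(self):
        rep = confusion_metrics(tp=0, fp=0, tn=10, fn=0)
        assert "tpr" in rep.undefined and "precision" in rep.undefined
        assert rep.tpr == 0.0

    def test_negative_counts(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 0, 1, 0)

    def test_swap_classes(self):
        a = confusion_metrics(10, 2, 30, 5)
        b = confusion_metrics(10, 2, 30, 5, swap_classes=True)
        assert b.tpr == a.tnr and b.tnr == a.tpr

    def test_roc_auc_is_rank_based(self):
        labels = [0, 0, 1, 1]
        assert roc_auc(labels, [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert roc_auc(labels, [0.9, 0.8, 0.2, 0.1]) == 0.0


class TestMeanRank:
    def test_identical_rows_tie(self):
        ranks = mean_rank([[0.5, 0.7], [0.5, 0.7]])
        assert list(ranks) == [1.5, 1.5]

    def test_single_method(self):
        assert list(mean_rank([[0.3, 0.9, 0.1]])) == [1.0]

    def test_descending_best_is_one(self):
        ranks = mean_rank([[0.9], [0.5], [0.1]])
        assert list(ranks) == [1.0, 2.0, 3.0]

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            mean_rank([[np.nan, 1.0], [0.5, 0.2]])


class TestWilcoxon:
    def test_degenerate_identical(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0],
                                   [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.degenerate
        assert res.pvalue == 1.0

    def test_exact_n5_all_positive(self):
        # two-sided exact p = 2 / 2^5
        res = wilcoxon_signed_rank([2.0, 3.0, 4.0, 5.0, 6.0],
                                   [1.0, 1.5, 2.0, 2.5, 3.0])
        assert res.pvalue == pytest.approx(0.0625)

    def test_exact_vs_approx_agree(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=15)
        b = a - 0.8 + rng.normal(scale=0.5, size=15)
        from scipy import stats

        exact = stats.wilcoxon(a - b, method="exact").pvalue
        approx = stats.wilcoxon(a - b, method="approx").pvalue
        ours = wilcoxon_signed_rank(a, b).pvalue
        assert ours == pytest.approx(exact)
        assert abs(exact - approx) < 0.01

    def test_too_few_nonzero(self):
        with pytest.raises(ValueError, match=">= 5"):
            wilcoxon_signed_rank([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])


# ----------------------------------------------------------------------
# tuning
# ----------------------------------------------------------------------

@pytest.fixture(scope="module")
def tune_table():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(80, 4))
    y = (X[:, 0] + 0.5 * rng.normal(size=80) > 0).astype(int)
    return numeric_table(X, y)


class TestTuneKNN:
    SPACE = {
        "n_neighbors": [1, 3, 5],
        "distance": ["euclidean", "cityblock"],
        "weighting": ["equal", "inverse"],
        "standardize": [False],
    }

    def test_full_budget_matches_grid_optimum(self, tune_table):
        from osadx.evaluation import error_rate

        cv = CVConfig(k=5, seed=1)
        best = tune_knn(tune_table, self.SPACE, budget=12, cv=cv, seed=0)
        # independent oracle: brute-force the grid with the same folds
        folds = make_folds(tune_table.y, cv)
        X, y = tune_table.to_matrix(), tune_table.y
        import itertools

        scored = []
        for combo in itertools.product(*self.SPACE.values()):
            spec = KNNSpec(**dict(zip(self.SPACE, combo)))
            scored.append(((error_rate(X, y, spec, folds), spec.n_neighbors), spec))
        oracle = min(scored, key=lambda t: t[0])
        assert best == oracle[1]

    def test_budget_one(self, tune_table):
        spec = tune_knn(tune_table, self.SPACE, budget=1,
                        cv=CVConfig(k=5, seed=1), seed=3)
        assert isinstance(spec, KNNSpec)

    def test_reproducible(self, tune_table):
        cv = CVConfig(k=5, seed=2)
        a = tune_knn(tune_table, self.SPACE, budget=5, cv=cv, seed=11)
        b = tune_knn(tune_table, self.SPACE, budget=5, cv=cv, seed=11)
        assert a == b

    def test_empty_space(self, tune_table):
        with pytest.raises(ValueError, match="empty"):
            tune_knn(tune_table, {"n_neighbors": []}, budget=3)


def test_preset_dispatch():
    rng = np.random.default_rng(0)
    X = rng.normal(size=(40, 3))
    y = (X[:, 0] > 0).astype(int)
    for name in ("DT", "LDA", "LR", "NB", "SVM", "MGSVM"):
        pred = predict(PresetSpec(name), (X, y), X[:5])
        assert pred.shape == (5,)
    with pytest.raises(ValueError):
        PresetSpec("KNB")
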