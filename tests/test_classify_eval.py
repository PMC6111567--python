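import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.model_selection import StratifiedKFold

from tfemotion.classify_eval import (
    ConfusionCounts,
    SVMHyperParams,
    _fit_svc,
    compute_metrics,
    confusion_matrix_metrics,
    cross_validate_subject,
    grid_search,
)


class TestMetrics:
    def test_hand_computed_binary_example(self):
        acc, f1 = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=1))
        assert acc == pytest.approx(100 * 5 / 7)
        assert f1 == pytest.approx(75.0)

    def test_perfect_and_all_wrong_predictions(self):
        assert compute_metrics(ConfusionCounts(5, 5, 0, 0)) == (100.0, 100.0)
        acc, f1 = compute_metrics(ConfusionCounts(0, 0, 5, 5))
        assert acc == 0.0 and f1 == 0.0

    def test_empty_counts_are_an_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_binary_confusion_matrix_reduces_to_the_count_formulas(self):
        # positive class is the "high" one (HA), wherever it sits in order
        classes = np.array(["HA", "LA"])
        matrix = np.array([[3, 1], [1, 2]])  # rows true, cols predicted
        acc, f1 = confusion_matrix_metrics(matrix, classes)
        expected = compute_metrics(ConfusionCounts(tp=3, tn=2, fp=1, fn=1))
        assert (acc, f1) == pytest.approx(expected)

    def test_multiclass_macro_f1(self):
        classes = np.array(["A", "B", "C"])
        matrix = np.array([[4, 1, 0], [0, 3, 2], [1, 0, 4]])
        acc, f1 = confusion_matrix_metrics(matrix, classes)
        assert acc == pytest.approx(100 * 11 / 15)
        f1_a = 2 * 4 / (2 * 4 + 1 + 1)
        f1_b = 2 * 3 / (2 * 3 + 1 + 2)
        f1_c = 2 * 4 / (2 * 4 + 2 + 1)
        assert f1 == pytest.approx(100 * (f1_a + f1_b + f1_c) / 3)


class TestGridSearch:
    def test_separable_blobs_reach_perfect_inner_accuracy(self):
        X, y = make_blobs(n_samples=60, centers=2, cluster_std=0.3, random_state=0)
        params = grid_search(X, y, c_grid=(1.0, 8.0), gamma_grid=(0.125, 1.0), seed=0)
        model = _fit_svc(X, y, params)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_single_point_grid_returns_that_point(self):
        X, y = make_blobs(n_samples=40, centers=2, random_state=1)
        params = grid_search(X, y, c_grid=(4.0,), gamma_grid=(0.5,), seed=0)
        assert params == SVMHyperParams(C=4.0, gamma=0.5)

    def test_ties_break_toward_smaller_c_then_smaller_gamma(self):
        # perfectly separable data scores 100% everywhere on the grid
        X, y = make_blobs(n_samples=60, centers=2, cluster_std=0.05, random_state=2)
        params = grid_search(X, y, c_grid=(8.0, 1.0, 64.0), gamma_grid=(2.0, 0.25), seed=0)
        assert params == SVMHyperParams(C=1.0, gamma=0.25)

    def test_single_class_training_set_is_an_error(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(ValueError, match="two classes"):
            grid_search(X, np.zeros(20))


class TestOneVsOne:
    @pytest.mark.parametrize("k", [2, 3, 4, 5])
    def test_k_classes_train_k_choose_2_binary_machines(self, k):
        X, y = make_blobs(n_samples=40 * k, centers=k, random_state=3)
        model = _fit_svc(X, y, SVMHyperParams(C=1.0, gamma=0.5))
        decisions = model.decision_function(X[:1])
        n_machines = 1 if decisions.ndim == 1 else decisions.shape[1]
        assert n_machines == k * (k - 1) // 2


class TestCrossValidation:
    def blobs(self, n=200, std=0.5, seed=0):
        X, y = make_blobs(n_samples=n, centers=2, cluster_std=std, random_state=seed)
        labels = np.array(["HA", "LA"])[y]
        return X, labels

    def test_folds_partition_the_samples(self):
        X, labels = self.blobs()
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=7)
        seen = np.concatenate([test for _, test in splitter.split(X, labels)])
        assert sorted(seen) == list(range(len(labels)))

    def test_fold_class_proportions_are_within_one_sample(self):
        X, labels = self.blobs(n=230)
        splitter = StratifiedKFold(n_splits=10, shuffle=True, random_state=7)
        _, counts = np.unique(labels, return_counts=True)
        for _, test in splitter.split(X, labels):
            _, fold_counts = np.unique(labels[test], return_counts=True)
            for share, fold in zip(counts / len(labels), fold_counts):
                assert abs(fold - share * len(test)) <= 1

    def test_strongly_separated_classes_score_high(self):
        X, labels = self.blobs(std=0.4)
        report = cross_validate_subject(
            X, labels, scheme="1D-2CLS-arousal", seed=1,
            c_grid=(1.0, 16.0), gamma_grid=(0.1, 1.0), inner_folds=3,
        )
        assert len(report.per_fold_acc) == 10
        assert report.mean_acc > 90.0
        assert report.mean_acc == pytest.approx(np.mean(report.per_fold_acc))

    def test_permuted_labels_score_near_chance(self):
        X, labels = self.blobs(std=0.4)
        permuted = np.random.default_rng(5).permutation(labels)
        report = cross_validate_subject(
            X, permuted, scheme="1D-2CLS-arousal", seed=1,
            c_grid=(1.0,), gamma_grid=(0.1,), inner_folds=3,
        )
        assert abs(report.mean_acc - 50.0) <= 10.0

    def test_reproducible_given_the_seed(self):
        X, labels = self.blobs(std=1.5, seed=4)
        kwargs = dict(scheme="1D-2CLS-arousal", seed=9, c_grid=(1.0, 4.0),
                      gamma_grid=(0.1,), inner_folds=3)
        r1 = cross_validate_subject(X, labels, **kwargs)
        r2 = cross_validate_subject(X, labels, **kwargs)
        assert r1.per_fold_acc == r2.per_fold_acc
        assert r1.chosen_params == r2.chosen_params

    def test_small_class_advises_merge_or_exclusion(self):
        X = np.random.default_rng(1).normal(size=(30, 3))
        labels = np.array(["HA"] * 25 + ["LA"] * 5)
        with pytest.raises(ValueError, match="merge or exclude"):
            cross_validate_subject(X, labels, scheme="1D-2CLS-arousal", seed=0)

    def test_per_fold_selection_keeps_test_data_unseen(self):
        # an informative column plus pure noise: with per-fold selection the
        # informative column must still be found from training data alone
        rng = np.random.default_rng(8)
        y = np.array(["HA", "LA"])[rng.integers(0, 2, size=200)]
        informative = (y == "HA") * 2.0 + rng.normal(scale=0.3, size=200)
        X = np.column_stack([informative] + [rng.normal(size=200) for _ in range(7)])
        report = cross_validate_subject(
            X, y, scheme="1D-2CLS-arousal", seed=2, selection_scenario="top25",
            c_grid=(1.0,), gamma_grid=(0.5,), inner_folds=3,
        )
        assert report.mean_acc > 90.0
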