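import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from bacv import (
    ClassifierModel,
    LabeledDataset,
    SignalSpec,
    compute_metrics,
    evaluate_independent,
    evaluate_loocv,
    fit_decision_tree,
    make_acv_dataset,
    rfe_select,
    train_svm,
)
from bacv.classify import metrics_from_predictions


def _toy_dataset(n=20, seed=0, n_features=6, separation=4.0):
    """Perfectly separable two-class data: feature 0 carries the classes apart."""
    rng = np.random.default_rng(seed)
    X = rng.poisson(2.0, size=(n, n_features)).astype(float)
    y = np.array([1, -1] * (n // 2))
    X[:, 0] += np.where(y == 1, separation, 0.0)
    labels = tuple(f"f{i}" for i in range(n_features))
    return LabeledDataset(X.astype(int), y, [f"s{i}" for i in range(n)], labels)


class TestComputeMetrics:
    def test_perfect_confusion(self):
        m = compute_metrics(10, 0, 10, 0)
        assert (m.recall, m.specificity, m.accuracy, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_ponstingl_style_confusion(self):
        # 76 dimers / 95 crystal packing with recall 0.934 and specificity 0.968
        m = compute_metrics(tp=71, fp=3, tn=92, fn=5)
        assert round(m.recall, 3) == 0.934
        assert round(m.specificity, 3) == 0.968
        assert round(m.accuracy, 3) == 0.953
        assert round(m.mcc, 3) == 0.905

    def test_fully_wrong_predictions(self):
        m = compute_metrics(0, 10, 0, 10)
        assert m.accuracy == 0.0
        assert m.mcc == -1.0

    def test_degenerate_denominator_reports_zero_with_flag(self):
        m = compute_metrics(5, 5, 0, 0)
        assert m.mcc == 0.0 and m.mcc_undefined

    def test_empty_positive_class_gives_nan_recall(self):
        m = compute_metrics(0, 2, 8, 0)
        assert np.isnan(m.recall)
        assert m.specificity == pytest.approx(0.8)

    @pytest.mark.parametrize("seed", range(5))
    def test_mcc_matches_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        y_true = rng.choice([-1, 1], size=50)
        y_pred = rng.choice([-1, 1], size=50)
        m = metrics_from_predictions(y_true, y_pred)
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))
        assert m.accuracy == pytest.approx(np.mean(y_true == y_pred))


class TestTrainSVM:
    def test_separating_weight_sign_and_training_accuracy(self):
        data = _toy_dataset()
        model = train_svm(data)
        assert model.weights[0] > 0  # feature 0 pushes toward the +1 class
        assert np.mean(model.predict(data) == data.y) == 1.0

    def test_duplicated_rows_leave_decision_function_unchanged(self):
        # in the hard-margin regime duplicating every row changes nothing:
        # the effective doubling of the slack penalty is inert
        data = _toy_dataset(separation=10.0)
        doubled = LabeledDataset(
            np.vstack([data.X, data.X]), np.concatenate([data.y, data.y]),
            data.ids + [f"{i}b" for i in data.ids], data.labels,
        )
        m1, m2 = train_svm(data, C=100.0), train_svm(doubled, C=100.0)
        np.testing.assert_allclose(
            m1.decision_function(data.X.astype(float)),
            m2.decision_function(data.X.astype(float)),
            atol=1e-6,
        )

    def test_planted_signal_training_accuracy(self, planted_dataset):
        model = train_svm(planted_dataset)
        assert np.mean(model.predict(planted_dataset) == planted_dataset.y) >= 0.95

    def test_single_class_data_rejected(self):
        data = _toy_dataset()
        bad = LabeledDataset(data.X, np.ones(len(data), dtype=int), data.ids, data.labels)
        with pytest.raises(ValueError, match="single class"):
            train_svm(bad)

    def test_model_json_roundtrip(self, tmp_path, small_planted_dataset):
        model = train_svm(small_planted_dataset)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClassifierModel.from_json(path)
        np.testing.assert_allclose(back.weights, model.weights)
        assert back.selected_features == model.selected_features
        np.testing.assert_array_equal(
            back.predict(small_planted_dataset), model.predict(small_planted_dataset)
        )


class TestRFE:
    def test_trace_covers_every_subset_size(self, small_planted_dataset):
        result = rfe_select(small_planted_dataset, seed=0)
        sizes = [s for s, _ in result.trace]
        assert sizes == list(range(len(small_planted_dataset.labels), 0, -1))
        assert len(result.elimination_order) == len(small_planted_dataset.labels) - 1

    def test_informative_features_survive(self, small_planted_dataset):
        spec_informative = {small_planted_dataset.labels[i] for i in (3, 17, 29)}
        result = rfe_select(small_planted_dataset, seed=0)
        assert len(spec_informative & set(result.selected_features)) >= 2

    def test_single_strong_feature_among_noise_selected(self):
        data = _toy_dataset(n=40, n_features=30, separation=8.0)
        hits = 0
        for seed in range(5):
            result = rfe_select(data, seed=seed)
            hits += "f0" in result.selected_features
        assert hits >= 4

    def test_zero_variance_features_eliminated_first(self):
        data = _toy_dataset(n=30, n_features=5)
        X = data.X.copy()
        X[:, 3] = 7  # constant column
        data = LabeledDataset(X, data.y, data.ids, data.labels)
        result = rfe_select(data, seed=1)
        assert result.elimination_order[0] == "f3"

    def test_all_noise_trace_hovers_near_chance(self):
        rng = np.random.default_rng(42)
        X = rng.poisson(2.0, size=(60, 10))
        y = np.array([1, -1] * 30)
        data = LabeledDataset(X, y, [f"s{i}" for i in range(60)],
                              tuple(f"f{i}" for i in range(10)))
        result = rfe_select(data, seed=0)
        accs = np.array([a for _, a in result.trace])
        # binomial noise around 0.5 at n=60: 4 sigma is ~0.26
        assert np.all(np.abs(accs - 0.5) < 0.26)


class TestLOOCV:
    def test_perfectly_separable_data_scores_one(self):
        data = _toy_dataset(n=16, separation=10.0)
        m = evaluate_loocv(data)
        assert m.accuracy == 1.0 and m.mcc == 1.0

    def test_minimal_four_sample_case(self):
        data = _toy_dataset(n=4, separation=10.0)
        m = evaluate_loocv(data)
        assert m.n == 4

    def test_row_order_invariance(self, small_planted_dataset):
        data = small_planted_dataset
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(data))
        shuffled = LabeledDataset(
            data.X[perm], data.y[perm], [data.ids[i] for i in perm], data.labels
        )
        m1, m2 = evaluate_loocv(data), evaluate_loocv(shuffled)
        assert m1.as_dict() == m2.as_dict()

    def test_permuted_labels_fall_to_chance(self):
        rng = np.random.default_rng(3)
        data = _toy_dataset(n=40, separation=6.0)
        permuted = LabeledDataset(
            data.X, rng.permutation(data.y), data.ids, data.labels
        )
        m = evaluate_loocv(permuted)
        majority = max(np.mean(permuted.y == 1), np.mean(permuted.y == -1))
        assert m.accuracy <= majority + 0.25  # within binomial noise of baseline


class TestIndependentEvaluation:
    def test_test_equals_train_for_perfect_model(self):
        data = _toy_dataset(separation=10.0)
        model = train_svm(data)
        m = evaluate_independent(model, data)
        assert m.accuracy == 1.0

    def test_same_generator_different_seed_close_to_loocv(self):
        train_data = make_acv_dataset(SignalSpec(n_per_class=50, n_features=40,
                                                 informative=(3, 11, 17, 23, 29), seed=21))
        test_data = make_acv_dataset(SignalSpec(n_per_class=50, n_features=40,
                                                informative=(3, 11, 17, 23, 29), seed=22))
        model = train_svm(train_data)
        ind = evaluate_independent(model, test_data)
        loo = evaluate_loocv(train_data)
        assert abs(ind.accuracy - loo.accuracy) <= 0.05

    def test_missing_feature_raises(self):
        data = _toy_dataset()
        model = train_svm(data)
        truncated = LabeledDataset(
            data.X[:, :3], data.y, data.ids, data.labels[:3]
        )
        with pytest.raises(ValueError, match="lacks model features"):
            model.predict(truncated)


class TestDecisionTree:
    def test_pure_class_data_gives_single_leaf(self):
        X = np.ones((10, 3), dtype=int)
        data = LabeledDataset(X, np.ones(10, dtype=int), [f"s{i}" for i in range(10)],
                              ("f0", "f1", "f2"))
        result = fit_decision_tree(data)
        assert result.tree.get_n_leaves() == 1

    def test_planted_threshold_rule_recovered(self):
        # class +1 iff slot "f2" count > 4: root must split f2 at 4
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.poisson(2.0, size=(80, 5))
            X[:40, 2] = rng.poisson(8.0, size=40).clip(min=5)
            X[40:, 2] = rng.integers(0, 5, size=40)
            y = np.array([1] * 40 + [-1] * 40)
            data = LabeledDataset(X, y, [f"s{i}" for i in range(80)],
                                  tuple(f"f{i}" for i in range(5)))
            result = fit_decision_tree(data, seed=seed)
            first_line = result.rules.splitlines()[0]
            hits += first_line.startswith("f2 <= 4")
        assert hits >= 6

    def test_tree_cv_not_wildly_above_svm(self, small_planted_dataset):
        result = fit_decision_tree(small_planted_dataset, seed=0)
        svm_model = train_svm(small_planted_dataset)
        svm_train_acc = np.mean(
            svm_model.predict(small_planted_dataset) == small_planted_dataset.y
        )
        assert result.cv_accuracy <= svm_train_acc + 0.1

    def test_rule_leaf_counts_sum_to_dataset(self):
        data = _toy_dataset(n=30, separation=6.0)
        result = fit_decision_tree(data, seed=0)
        totals = [
            int(line.split("(")[1].split("/")[0])
            for line in result.rules.splitlines()
            if "(" in line
        ]
        assert sum(totals) == len(data)
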