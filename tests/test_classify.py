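import numpy as np
import pytest

from pcgkit import (
    LabeledDataset,
    ParameterError,
    TrainingError,
    confusion_metrics,
    kfold_cross_validate,
    predict,
    roc_auc,
    train_linear_svm,
)
from pcgkit.classify import stratified_folds


def brute_force_auc(scores, labels):
    """Concordance probability over all (positive, negative) pairs, ties = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == -1]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def separable_clusters(n_per_class=20, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(n_per_class, 2)) + np.array([0.0, 0.0])
    b = rng.normal(size=(n_per_class, 2)) + np.array([10.0, 10.0])
    x = np.vstack([a, b])
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    return LabeledDataset(x, y)


class TestTrainLinearSvm:
    def test_two_point_analytic_solution(self):
        data = LabeledDataset(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        model = train_linear_svm(data, standardize=False)
        assert model.w[0] == pytest.approx(1.0, abs=1e-6)
        assert model.b == pytest.approx(0.0, abs=1e-6)
        assert model.margin == pytest.approx(2.0, rel=1e-6)

    def test_separable_clusters_train_accuracy_100(self):
        data = separable_clusters()
        model = train_linear_svm(data)
        labels, _ = predict(model, data.features)
        assert np.array_equal(labels, data.labels)

    def test_single_class_rejected(self):
        with pytest.raises(TrainingError):
            train_linear_svm(LabeledDataset(np.zeros((4, 2)), np.ones(4, dtype=int)))

    def test_nonfinite_features_rejected(self):
        from pcgkit.errors import ValidationError

        with pytest.raises(ValidationError):
            LabeledDataset(np.array([[np.inf], [0.0]]), np.array([1, -1]))


class TestPredict:
    def test_boundary_tie_goes_healthy(self):
        data = LabeledDataset(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        model = train_linear_svm(data, standardize=False)
        labels, dec = predict(model, np.array([[0.0]]))
        assert dec[0] == pytest.approx(0.0, abs=1e-9)
        assert labels[0] == 1

    def test_training_points_decision_values(self):
        data = LabeledDataset(np.array([[-1.0], [1.0]]), np.array([-1, 1]))
        model = train_linear_svm(data, standardize=False)
        _, dec = predict(model, data.features)
        assert dec == pytest.approx([-1.0, 1.0], abs=1e-6)

    def test_dimension_mismatch(self):
        model = train_linear_svm(separable_clusters())
        with pytest.raises(ParameterError):
            predict(model, np.zeros((3, 5)))

    def test_stored_scaling_makes_prediction_self_contained(self):
        data = separable_clusters(seed=2)
        model = train_linear_svm(data)
        raw_labels, raw_dec = predict(model, data.features)
        pre_scaled = (data.features - model.center) / model.scale
        manual = pre_scaled @ model.w - model.b
        assert np.allclose(manual, raw_dec)


class TestConfusionMetrics:
    def test_reported_clinical_matrix(self):
        acc, per_class = confusion_metrics([[56, 2], [7, 51]])
        assert acc == pytest.approx(92.2, abs=0.05)
        assert per_class[0] == pytest.approx(96.6, abs=0.05)
        assert per_class[1] == pytest.approx(87.9, abs=0.05)

    def test_perfect_matrix(self):
        acc, per_class = confusion_metrics([[58, 0], [0, 58]])
        assert acc == 100.0
        assert per_class == (100.0, 100.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            confusion_metrics([[0, 0], [0, 0]])


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([2.0, 1.5, -1.0, -2.0])
        labels = np.array([1, 1, -1, -1])
        points, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(1.0)
        assert tuple(points[0]) == (0.0, 0.0) and tuple(points[-1]) == (1.0, 1.0)

    def test_constant_scores_auc_half(self):
        _, auc = roc_auc(np.zeros(6), np.array([1, -1, 1, -1, 1, -1]))
        assert auc == pytest.approx(0.5)

    def test_hand_computed_three_quarters(self):
        _, auc = roc_auc(np.array([0.9, 0.8, 0.3, 0.1]), np.array([1, -1, 1, -1]))
        assert auc == pytest.approx(0.75)

    def test_roc_monotone(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=50)
        labels = np.where(rng.uniform(size=50) > 0.5, 1, -1)
        points, _ = roc_auc(scores, labels)
        assert np.all(np.diff(points[:, 0]) >= 0)
        assert np.all(np.diff(points[:, 1]) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            roc_auc(np.array([1.0, 2.0]), np.array([1, 1]))

    def test_matches_brute_force_concordance_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(2, 13))
            scores = rng.integers(0, 4, size=n).astype(float)  # many ties
            labels = np.where(rng.uniform(size=n) > 0.5, 1, -1)
            if np.unique(labels).size < 2:
                continue
            _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)


class TestKfoldCrossValidate:
    def test_fold_sizes_for_116_recordings(self):
        y = np.array([1] * 58 + [-1] * 58)
        folds = stratified_folds(y, k=8, seed=0)
        sizes = sorted(np.bincount(folds, minlength=8).tolist())
        assert sizes == [14, 14, 14, 14, 15, 15, 15, 15]
        # stratified: each fold holds 7-8 members of each class
        for f in range(8):
            per_class = np.bincount((y[folds == f] == 1).astype(int), minlength=2)
            assert set(per_class.tolist()) <= {7, 8}

    def test_separable_data_perfect_report(self):
        data = separable_clusters(n_per_class=24, seed=3)
        report = kfold_cross_validate(data, k=8, seed=1)
        assert report.accuracy == 100.0
        assert report.auc == pytest.approx(1.0)
        assert report.confusion.sum() == 48

    def test_determinism(self):
        data = separable_clusters(n_per_class=16, seed=4)
        r1 = kfold_cross_validate(data, k=4, seed=5)
        r2 = kfold_cross_validate(data, k=4, seed=5)
        assert np.array_equal(r1.fold_assignments, r2.fold_assignments)
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_k_larger_than_class_rejected(self):
        data = separable_clusters(n_per_class=3)
        with pytest.raises(ParameterError):
            kfold_cross_validate(data, k=5, seed=0)

    def test_no_leakage_from_test_fold(self):
        """Perturbing one test-fold feature must not change decisions for
        other members of that fold (standardization is fit on train only)."""
        data = separable_clusters(n_per_class=16, seed=6)
        folds = stratified_folds(data.labels, k=4, seed=7)
        target_fold = 0
        members = np.nonzero(folds == target_fold)[0]
        perturbed = data.features.copy()
        perturbed[members[0]] += 1e6
        r1 = kfold_cross_validate(data, k=4, seed=7)
        r2 = kfold_cross_validate(LabeledDataset(perturbed, data.labels), k=4, seed=7)

        # recompute decisions for the untouched members of the fold
        def decisions(report, dataset):
            from pcgkit.classify import train_linear_svm as fit

            train = folds != target_fold
            model = fit(LabeledDataset(dataset.features[train], dataset.labels[train]))
            _, dec = predict(model, dataset.features[members[1:]])
            return dec

        assert np.allclose(decisions(r1, data), decisions(r2, LabeledDataset(perturbed, data.labels)))
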