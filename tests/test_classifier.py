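"""Node training, cascade prediction and evaluation."""

import numpy as np
import pytest
from sklearn.svm import SVC

from dtsvm import (
    RADAR_FEATURES,
    SVMConfig,
    build_tree,
    evaluate,
    fit_dtsvm,
    load_model,
    predict,
    save_model,
    train,
)
from tests.conftest import toy_dataset


@pytest.fixture(scope="module")
def trained_small(small_cohort_module):
    train_set, test_set = small_cohort_module
    tree = fit_dtsvm(train_set.select_features(RADAR_FEATURES))
    return tree, train_set, test_set


@pytest.fixture(scope="module")
def small_cohort_module():
    from dtsvm import GenerationConfig, generate_cohort, load_species_stats, split_train_test

    cohort = generate_cohort(
        load_species_stats(), GenerationConfig(samples_per_class=200, rng_seed=11)
    )
    return split_train_test(cohort, seed=12)


class TestTrain:
    def test_separable_classes_perfect_training_accuracy(self, two_blob_dataset):
        tree = fit_dtsvm(two_blob_dataset)
        report = evaluate(predict(tree, two_blob_dataset), two_blob_dataset.labels)
        assert report.mean_accuracy == 1.0

    def test_high_wingbeat_species_perfect_on_training(self, trained_small):
        # species S (wingbeat 182-289 Hz, all others below 156 Hz) is
        # perfectly recovered even on resubstitution
        tree, train_set, _ = trained_small
        three = train_set.select_features(RADAR_FEATURES)
        report = evaluate(predict(tree, three), three.labels)
        assert report.per_species_accuracy["S"] == 1.0

    def test_retraining_is_deterministic(self, small_cohort_module):
        train_set, test_set = small_cohort_module
        probe = test_set.select_features(RADAR_FEATURES)
        a = fit_dtsvm(train_set.select_features(RADAR_FEATURES))
        b = fit_dtsvm(train_set.select_features(RADAR_FEATURES))
        np.testing.assert_array_equal(predict(a, probe), predict(b, probe))

    def test_feature_mismatch_rejected(self, trained_small, two_blob_dataset):
        tree, train_set, _ = trained_small
        with pytest.raises(ValueError, match="do not match"):
            train(tree, train_set)  # 4-feature data on a 3-feature tree


class TestPredict:
    def test_cascade_reaches_exactly_one_leaf_each(self, trained_small):
        tree, _, test_set = trained_small
        three = test_set.select_features(RADAR_FEATURES)
        out = predict(tree, three)
        assert out.shape == (three.n_samples,)
        assert set(out) <= set(tree.species())

    def test_species_mean_vectors_classified_correctly(self, stats, trained_small):
        tree, _, _ = trained_small
        means = np.array(
            [[sp.feature(f).mean for f in RADAR_FEATURES] for sp in stats]
        )
        out = predict(tree, means)
        expected = [sp.label for sp in stats]
        assert list(out) == expected

    def test_single_node_tree_equals_bare_svm(self, two_blob_dataset):
        """A 2-class DTSVM is exactly the underlying binary SVM."""
        cfg = SVMConfig()
        tree = fit_dtsvm(two_blob_dataset, cfg)
        x = tree.scaler.transform(two_blob_dataset.features)
        side = np.isin(
            two_blob_dataset.labels, sorted(tree.root.right.labels)
        ).astype(int)
        bare = cfg.make().fit(x, side)
        probe = np.linspace(-5, 15, 300).reshape(-1, 1)
        cascade = predict(tree, probe)
        flat = bare.predict(tree.scaler.transform(probe))
        mapped = np.where(flat == 0, tree.root.left.species, tree.root.right.species)
        np.testing.assert_array_equal(cascade, mapped)

    def test_empty_matrix_gives_empty_predictions(self, trained_small):
        tree, _, _ = trained_small
        assert predict(tree, np.empty((0, 3))).shape == (0,)

    def test_wrong_feature_count_rejected(self, trained_small):
        tree, _, _ = trained_small
        with pytest.raises(ValueError, match="3 features"):
            predict(tree, np.zeros((2, 4)))

    def test_untrained_tree_rejected(self, two_blob_dataset):
        tree = build_tree(two_blob_dataset)
        with pytest.raises(ValueError, match="untrained"):
            predict(tree, two_blob_dataset.features)


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array(["A", "B", "B", "C"])
        report = evaluate(y, y)
        assert report.mean_accuracy == 1.0
        assert all(v == 1.0 for v in report.per_species_accuracy.values())
        assert (np.diag(report.confusion) == [1, 2, 1]).all()

    def test_recall_definition_and_unweighted_mean(self):
        truth = np.array(["A"] * 4 + ["B"] * 2)
        pred = np.array(["A", "A", "A", "B", "B", "B"])
        report = evaluate(pred, truth)
        assert report.per_species_accuracy == {"A": 0.75, "B": 1.0}
        assert report.mean_accuracy == pytest.approx((0.75 + 1.0) / 2)

    def test_confusion_rows_conserve_counts(self, trained_small):
        tree, _, test_set = trained_small
        three = test_set.select_features(RADAR_FEATURES)
        report = evaluate(predict(tree, three), three.labels)
        counts = three.class_counts()
        for label, row_sum in report.confusion.sum(axis=1).items():
            assert row_sum == counts[label]

    def test_unknown_predicted_label_rejected(self):
        with pytest.raises(ValueError, match="unknown label"):
            evaluate(np.array(["A", "Z"]), np.array(["A", "A"]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            evaluate(np.array(["A"]), np.array(["A", "B"]))


class TestModelArchive:
    def test_save_load_round_trip(self, tmp_path, trained_small):
        tree, _, test_set = trained_small
        three = test_set.select_features(RADAR_FEATURES)
        path = tmp_path / "model.joblib"
        save_model(tree, path)
        loaded = load_model(path)
        np.testing.assert_array_equal(predict(loaded, three), predict(tree, three))

    def test_non_model_archive_rejected(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"not": "a model"}, path)
        with pytest.raises(ValueError, match="DTSVM"):
            load_model(path)
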