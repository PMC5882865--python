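"""Cohort generation moments, reproducibility and splitting."""

import numpy as np
import pytest

from dtsvm import (
    FEATURE_NAMES,
    RADAR_FEATURES,
    GenerationConfig,
    generate_cohort,
    split_train_test,
)
from dtsvm.feature_data import FeatureSummary, SpeciesStats


def point_species(label, means, std=0.0):
    feats = {
        f: FeatureSummary(mean=m, std=std, range_min=m - 3, range_max=m + 3)
        for f, m in zip(FEATURE_NAMES, means)
    }
    return SpeciesStats(label, label, "fam", "ord", 10, feats)


class TestGenerateCohort:
    def test_counts_conserved(self, stats):
        cohort = generate_cohort(
            stats, GenerationConfig(samples_per_class=50, rng_seed=0)
        )
        assert cohort.n_samples == 23 * 50
        assert set(cohort.class_counts().values()) == {50}

    def test_moments_recover_statistics(self, stats, small_cohort):
        # |sample mean - mean| <= 4 std/sqrt(n) per species and feature
        cohort = generate_cohort(
            stats, GenerationConfig(samples_per_class=5000, rng_seed=5)
        )
        for sp in stats:
            block = cohort.features[cohort.labels == sp.label]
            for j, feat in enumerate(FEATURE_NAMES):
                summ = sp.feature(feat)
                tol = 4 * summ.std / np.sqrt(5000)
                assert abs(block[:, j].mean() - summ.mean) <= tol, (sp.label, feat)

    def test_high_wingbeat_species_mean_converges(self, stats_by_label):
        # species S: wingbeat mean 233.40 Hz recovered within 0.5 Hz at n=1e5
        cohort = generate_cohort(
            [stats_by_label["S"]],
            GenerationConfig(samples_per_class=100_000, rng_seed=2),
        )
        assert cohort.column("wingbeat_frequency").mean() == pytest.approx(
            233.40, abs=0.5
        )

    def test_zero_std_degenerate(self):
        sp = point_species("z", [10.0, 20.0, 3.0, 5.0])
        cohort = generate_cohort(
            [sp], GenerationConfig(samples_per_class=2, rng_seed=0)
        )
        np.testing.assert_array_equal(
            cohort.features, [[10.0, 20.0, 3.0, 5.0]] * 2
        )

    def test_reproducible_under_seed(self, stats):
        cfg = GenerationConfig(samples_per_class=30, rng_seed=42)
        a = generate_cohort(stats, cfg)
        b = generate_cohort(stats, cfg)
        np.testing.assert_array_equal(a.features, b.features)

    def test_feature_subsets_share_columns(self, stats):
        """3-feature cohorts are the 4-feature cohorts' shared columns."""
        four = generate_cohort(
            stats, GenerationConfig(samples_per_class=40, rng_seed=9)
        )
        three = generate_cohort(
            stats,
            GenerationConfig(
                samples_per_class=40, rng_seed=9, feature_names=RADAR_FEATURES
            ),
        )
        np.testing.assert_array_equal(
            three.features, four.select_features(RADAR_FEATURES).features
        )

    def test_independent_features_uncorrelated(self, stats_by_label):
        cohort = generate_cohort(
            [stats_by_label["B"]],
            GenerationConfig(samples_per_class=20_000, rng_seed=3),
        )
        corr = np.corrcoef(cohort.features.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 0.03

    def test_supplied_correlation_is_realised(self, stats_by_label):
        r = 0.8
        corr = np.eye(4)
        corr[0, 3] = corr[3, 0] = r  # mass vs body length
        cohort = generate_cohort(
            [stats_by_label["B"]],
            GenerationConfig(
                samples_per_class=20_000,
                rng_seed=4,
                correlation_mode={"B": corr},
            ),
        )
        sample_r = np.corrcoef(cohort.column("mass"), cohort.column("body_length"))[0, 1]
        assert sample_r == pytest.approx(r, abs=0.03)

    def test_all_values_positive(self, stats):
        # species U has mass mean 14.52, std 2.79: negatives must be resampled
        cohort = generate_cohort(
            stats, GenerationConfig(samples_per_class=2000, rng_seed=6)
        )
        assert (cohort.features > 0).all()

    def test_truncate_to_range(self, stats_by_label):
        sp = stats_by_label["B"]
        cohort = generate_cohort(
            [sp],
            GenerationConfig(
                samples_per_class=5000, rng_seed=7, truncate_to_range=True
            ),
        )
        for feat in FEATURE_NAMES:
            summ = sp.feature(feat)
            col = cohort.column(feat)
            assert col.min() >= summ.range_min and col.max() <= summ.range_max

    def test_missing_feature_reports_species(self):
        sp = point_species("q", [1, 2, 3, 4])
        broken = SpeciesStats(
            "q", "q", "fam", "ord", 10,
            {k: v for k, v in sp.features.items() if k != "body_length"},
        )
        with pytest.raises(ValueError, match="'q'.*body_length"):
            generate_cohort([broken], GenerationConfig(samples_per_class=5))


class TestSplitTrainTest:
    def test_even_split_per_class(self, small_cohort):
        train, test = split_train_test(small_cohort, seed=1)
        assert set(train.class_counts().values()) == {100}
        assert set(test.class_counts().values()) == {100}

    def test_union_is_input_intersection_empty(self, small_cohort):
        train, test = split_train_test(small_cohort, seed=1)
        combined = np.vstack([train.features, test.features])
        assert combined.shape == small_cohort.features.shape
        pool = {tuple(r) for r in small_cohort.features}
        assert {tuple(r) for r in combined} == pool
        assert not ({tuple(r) for r in train.features} & {tuple(r) for r in test.features})

    def test_odd_count_extra_goes_to_training(self, two_blob_dataset):
        ds = two_blob_dataset.subset(np.arange(99))  # 50 'a' + 49 'b'
        train, test = split_train_test(ds, seed=0)
        assert train.class_counts() == {"a": 25, "b": 25}
        assert test.class_counts() == {"a": 25, "b": 24}

    def test_singleton_class_rejected(self, two_blob_dataset):
        ds = two_blob_dataset.subset(np.arange(51))  # 'b' has one sample
        with pytest.raises(ValueError, match="'b'"):
            split_train_test(ds, seed=0)

    def test_input_order_does_not_change_counts(self, small_cohort):
        rng = np.random.default_rng(0)
        shuffled = small_cohort.subset(rng.permutation(small_cohort.n_samples))
        t1, _ = split_train_test(small_cohort, seed=5)
        t2, _ = split_train_test(shuffled, seed=5)
        assert t1.class_counts() == t2.class_counts()
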