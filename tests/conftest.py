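import numpy as np
import pytest

from dtsvm import (
    FEATURE_NAMES,
    GenerationConfig,
    LabeledDataset,
    generate_cohort,
    load_species_stats,
    split_train_test,
)


@pytest.fixture(scope="session")
def stats():
    return load_species_stats()


@pytest.fixture(scope="session")
def stats_by_label(stats):
    return {s.label: s for s in stats}


@pytest.fixture(scope="session")
def small_cohort(stats):
    """All 23 species, 200 samples each, all four features."""
    return generate_cohort(
        stats, GenerationConfig(samples_per_class=200, rng_seed=11)
    )


@pytest.fixture(scope="session")
def small_split(small_cohort):
    return split_train_test(small_cohort, seed=12)


def toy_dataset(centers, sigmas, n_per_class, seed=0, labels=None):
    """Gaussian blobs with given centers (k x d) and scalar sigmas."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    rng = np.random.default_rng(seed)
    labels = labels or [chr(ord("a") + i) for i in range(len(centers))]
    feats, labs = [], []
    for c, s, lab in zip(centers, np.broadcast_to(sigmas, len(centers)), labels):
        feats.append(c + s * rng.standard_normal((n_per_class, centers.shape[1])))
        labs.extend([lab] * n_per_class)
    names = FEATURE_NAMES[: centers.shape[1]]
    return LabeledDataset(np.vstack(feats), np.array(labs), names)


@pytest.fixture
def two_blob_dataset():
    return toy_dataset([[0.0], [10.0]], 1.0, 50, seed=3)
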