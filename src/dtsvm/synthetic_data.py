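"""Gaussian cohort generation from per-species summary statistics.

Real trapped-specimen counts per species are small and uneven, so the study
design extends every species to a fixed-size cohort by sampling from a normal
distribution parameterised by the species' measured mean and standard
deviation, then splits each cohort 50/50 into training and testing halves.

Per-species covariances of the raw specimens are not available, so the
default generator draws each feature independently (diagonal covariance from
the printed standard deviations).  Users holding raw specimen data can supply
full per-species correlation matrices instead.

Reproducibility: every (species, feature) pair draws from its own
deterministic substream derived from the master seed, so cohorts generated
for a feature subset share identical columns with cohorts generated for a
superset at the same seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .feature_data import (
    FEATURE_NAMES,
    LabeledDataset,
    SpeciesStats,
    canonical_order,
)

_MAX_RESAMPLE_ROUNDS = 1000


def _label_key(label: str) -> int:
    """Stable non-negative integer identifying a species label."""
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class GenerationConfig:
    """Settings for synthetic cohort generation.

    Parameters
    ----------
    samples_per_class
        Cohort size per species; the study value is 5000.
    feature_names
        Ordered subset of the four canonical features to generate.
    correlation_mode
        ``"independent"`` (default) for diagonal covariance, or a mapping
        ``label -> correlation matrix`` (in the order of ``feature_names``)
        for users with raw specimen data.
    rng_seed
        Master seed for the generator.
    truncate_to_range
        If true, resample any draw falling outside the species' printed
        min-max range for a feature.  Off by default: the study's
        distribution curves are smooth Gaussians, suggesting no truncation.
    """

    samples_per_class: int = 5000
    feature_names: tuple[str, ...] = FEATURE_NAMES
    correlation_mode: str | Mapping[str, np.ndarray] = "independent"
    rng_seed: int = 0
    truncate_to_range: bool = False

    def __post_init__(self) -> None:
        if self.samples_per_class < 2:
            raise ValueError("samples_per_class must be at least 2")
        if not self.feature_names:
            raise ValueError("feature set must be non-empty")
        object.__setattr__(
            self, "feature_names", canonical_order(self.feature_names)
        )


def _resample_mask(
    rng: np.random.Generator,
    values: np.ndarray,
    draw: callable,
    invalid: callable,
    context: str,
) -> np.ndarray:
    """Redraw entries of *values* where *invalid* holds, a bounded number of times."""
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        mask = invalid(values)
        if not mask.any():
            return values
        values[mask] = draw(int(mask.sum()))
    raise RuntimeError(f"resampling failed to produce valid draws for {context}")


def _generate_independent(
    sp: SpeciesStats, config: GenerationConfig
) -> np.ndarray:
    n = config.samples_per_class
    cols = []
    for feat in config.feature_names:
        summ = sp.feature(feat)
        # substream keyed by canonical feature index => feature subsets share columns
        ss = np.random.SeedSequence(
            [config.rng_seed, _label_key(sp.label), FEATURE_NAMES.index(feat)]
        )
        rng = np.random.default_rng(ss)
        draw = lambda k: summ.mean + summ.std * rng.standard_normal(k)
        x = draw(n)
        if summ.std > 0:
            # physical features are strictly positive: resample, never clip
            invalid = lambda v: v <= 0
            if config.truncate_to_range and not sp.range_suspect:
                invalid = lambda v: (v <= 0) | (v < summ.range_min) | (v > summ.range_max)
            x = _resample_mask(rng, x, draw, invalid, f"{sp.label}/{feat}")
        cols.append(x)
    return np.column_stack(cols)


def _generate_correlated(
    sp: SpeciesStats, corr: np.ndarray, config: GenerationConfig
) -> np.ndarray:
    names = config.feature_names
    mean = np.array([sp.feature(f).mean for f in names])
    std = np.array([sp.feature(f).std for f in names])
    corr = np.asarray(corr, dtype=float)
    if corr.shape != (len(names), len(names)):
        raise ValueError(
            f"correlation matrix for species {sp.label!r} must be "
            f"{len(names)}x{len(names)}"
        )
    cov = np.outer(std, std) * corr
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed, _label_key(sp.label)])
    )
    draw = lambda k: rng.multivariate_normal(mean, cov, size=k, method="svd")
    x = draw(config.samples_per_class)
    for _ in range(_MAX_RESAMPLE_ROUNDS):
        bad = (x <= 0).any(axis=1)
        if config.truncate_to_range and not sp.range_suspect:
            lo = np.array([sp.feature(f).range_min for f in names])
            hi = np.array([sp.feature(f).range_max for f in names])
            bad |= ((x < lo) | (x > hi)).any(axis=1)
        if not bad.any():
            return x
        x[bad] = draw(int(bad.sum()))
    raise RuntimeError(f"resampling failed for species {sp.label!r}")


def generate_cohort(
    stats: Sequence[SpeciesStats], config: GenerationConfig | None = None
) -> LabeledDataset:
    """Generate a fixed-size Gaussian cohort for every species in *stats*.

    Returns a :class:`LabeledDataset` with ``samples_per_class`` rows per
    species, features in canonical order, rows grouped by species in label
    order.  Sample moments converge to the input statistics as the cohort
    grows; generation is reproducible under a fixed seed.
    """
    config = config or GenerationConfig()
    blocks, labels = [], []
    for sp in sorted(stats, key=lambda s: s.label):
        for feat in config.feature_names:
            if feat not in sp.features:
                raise ValueError(
                    f"species {sp.label!r} lacks statistics for feature {feat!r}"
                )
        if isinstance(config.correlation_mode, str):
            if config.correlation_mode != "independent":
                raise ValueError(
                    f"unknown correlation_mode {config.correlation_mode!r}"
                )
            block = _generate_independent(sp, config)
        else:
            if sp.label not in config.correlation_mode:
                raise ValueError(
                    f"no correlation matrix supplied for species {sp.label!r}"
                )
            block = _generate_correlated(
                sp, config.correlation_mode[sp.label], config
            )
        blocks.append(block)
        labels.extend([sp.label] * config.samples_per_class)
    return LabeledDataset(
        np.vstack(blocks), np.array(labels), config.feature_names
    )


def split_train_test(
    dataset: LabeledDataset, seed: int = 0
) -> tuple[LabeledDataset, LabeledDataset]:
    """Stratified 50/50 split of *dataset* into (train, test).

    Each class is shuffled and halved independently; with an odd class count
    the extra sample goes to training.  The union of the halves is the input
    and their intersection is empty.
    """
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in dataset.classes():
        idx = np.flatnonzero(dataset.labels == label)
        if len(idx) < 2:
            raise ValueError(
                f"class {label!r} has {len(idx)} sample(s); need at least 2 to split"
            )
        perm = rng.permutation(idx)
        n_train = (len(idx) + 1) // 2
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (
        dataset.subset(np.concatenate(train_idx)),
        dataset.subset(np.concatenate(test_idx)),
    )
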