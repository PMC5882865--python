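"""Class centers, scalar spreads and the inter-class separability factor.

The separability of two classes (or merged class groups) i and j is measured
by the inter-class separability factor (ICSF)

    dm_ij = d(m_i, m_j) / (sigma_i + sigma_j)

where d is the Euclidean distance between the class centers m_i, m_j and
sigma_i is a scalar spread of class i.  The center is the arithmetic mean of
the class samples (the k=1 K-means fixed point).  The scalar spread is
defined here as sigma_i^2 = trace of the per-class sample covariance (sum of
per-feature variances, n-1 normalisation): the unique rotation-invariant
scalar consistent with the Euclidean distance in the numerator.

Because the raw features span orders of magnitude (mass up to ~500 mg versus
a unitless ratio below 13), Euclidean distance on raw features would be
mass-dominated; z-score standardisation fitted on training data is therefore
applied before ICSF computation and SVM training by default.

ICSF is scale-covariant: rescaling all features by a common factor rescales
distance and spreads alike, leaving dm_ij unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .feature_data import LabeledDataset


@dataclass(frozen=True)
class Scaler:
    """Per-feature location/scale fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray
    feature_names: tuple[str, ...]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim != 2 or x.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected a matrix with {len(self.feature_names)} columns, "
                f"got shape {x.shape}"
            )
        return (x - self.mean) / self.scale

    def transform_dataset(self, dataset: LabeledDataset) -> LabeledDataset:
        if dataset.feature_names != self.feature_names:
            raise ValueError(
                f"dataset features {dataset.feature_names} do not match "
                f"scaler features {self.feature_names}"
            )
        return LabeledDataset(
            self.transform(dataset.features), dataset.labels, dataset.feature_names
        )


def standardize(dataset: LabeledDataset) -> tuple[LabeledDataset, Scaler]:
    """Z-score each feature over the full dataset; return data and parameters.

    Raises ``ValueError`` naming the feature if any column has zero variance.
    """
    mean = dataset.features.mean(axis=0)
    scale = dataset.features.std(axis=0)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        raise ValueError(
            f"zero-variance feature(s): {[dataset.feature_names[i] for i in zero]}"
        )
    scaler = Scaler(mean=mean, scale=scale, feature_names=dataset.feature_names)
    return scaler.transform_dataset(dataset), scaler


@dataclass(frozen=True)
class ClassGroup:
    """A (possibly merged) class group: member labels, center and spread."""

    labels: frozenset[str]
    center: np.ndarray
    sigma: float
    n_samples: int


def group_center_and_sigma(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """Center (mean vector) and scalar spread of one group's sample matrix.

    sigma^2 is the trace of the sample covariance (n-1 normalisation); a
    single sample has sigma 0.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] == 0:
        raise ValueError("cannot compute center of an empty group")
    center = samples.mean(axis=0)
    if samples.shape[0] == 1:
        return center, 0.0
    sigma = float(np.sqrt(samples.var(axis=0, ddof=1).sum()))
    return center, sigma


def make_group(labels: Iterable[str], samples: np.ndarray) -> ClassGroup:
    center, sigma = group_center_and_sigma(samples)
    return ClassGroup(
        labels=frozenset(labels),
        center=center,
        sigma=sigma,
        n_samples=np.atleast_2d(samples).shape[0],
    )


def icsf(group_i: ClassGroup, group_j: ClassGroup) -> float:
    """Inter-class separability factor between two groups (symmetric, >= 0).

    Degenerate cases: if both spreads are zero, coincident centers raise
    (identical point classes are inseparable) and distinct centers return
    ``inf``.
    """
    d = float(np.linalg.norm(group_i.center - group_j.center))
    denom = group_i.sigma + group_j.sigma
    if denom == 0.0:
        if d == 0.0:
            raise ValueError(
                f"groups {sorted(group_i.labels)} and {sorted(group_j.labels)} "
                "are identical degenerate classes (zero spread, same center)"
            )
        return float("inf")
    return d / denom


@dataclass
class SeparabilityMatrix:
    """Pairwise ICSF values between an ordered list of class groups."""

    groups: list[ClassGroup]
    values: np.ndarray  # symmetric, NaN diagonal

    def to_dataframe(self) -> pd.DataFrame:
        names = ["+".join(sorted(g.labels)) for g in self.groups]
        return pd.DataFrame(self.values, index=names, columns=names)

    def min_pair(self) -> tuple[int, int, float]:
        """Indices and value of the least-separable pair (deterministic
        tie-break: lexicographically smallest merged label string)."""
        k = len(self.groups)
        best: tuple[float, str, int, int] | None = None
        for i in range(k):
            for j in range(i + 1, k):
                key = "".join(sorted(self.groups[i].labels | self.groups[j].labels))
                cand = (float(self.values[i, j]), key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        assert best is not None
        return best[2], best[3], best[0]


def separability_matrix(
    dataset: LabeledDataset,
    grouping: Sequence[Iterable[str]] | None = None,
) -> SeparabilityMatrix:
    """All pairwise ICSF values for a partition of the dataset's labels.

    *grouping* is a sequence of label sets (default: one singleton group per
    class).  Group statistics are computed from the pooled samples of each
    group's member classes.
    """
    if grouping is None:
        grouping = [{c} for c in dataset.classes()]
    groups = []
    for labels in grouping:
        labels = set(labels)
        mask = np.isin(dataset.labels, sorted(labels))
        if not mask.any():
            raise ValueError(f"group {sorted(labels)} has no samples")
        groups.append(make_group(labels, dataset.features[mask]))
    k = len(groups)
    values = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            values[i, j] = values[j, i] = icsf(groups[i], groups[j])
    return SeparabilityMatrix(groups=groups, values=values)
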