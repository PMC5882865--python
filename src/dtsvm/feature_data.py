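"""Domain types and I/O for radar-observable insect features.

The package works with four morphometric features that entomological radar
can (or could plausibly) retrieve from airborne insects:

========================  ========  =============================================
feature                   unit      meaning
========================  ========  =============================================
mass                      mg        body mass, retrieved from radar cross-section
wingbeat_frequency        Hz        wing oscillation rate, from echo modulation
length_to_width_ratio     (none)    body shape descriptor
body_length               mm        body length (not yet radar-retrievable)
========================  ========  =============================================

The canonical feature order is the order above and is fixed everywhere in the
package.  A bundled fixture carries per-species summary statistics (mean,
standard deviation, observed min-max range) for 23 migratory insect species
trapped in the Bohai Gulf migration corridor; these statistics are the sole
input needed to regenerate the study's synthetic cohorts.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical feature order, fixed across the whole package.
FEATURE_NAMES: tuple[str, ...] = (
    "mass",
    "wingbeat_frequency",
    "length_to_width_ratio",
    "body_length",
)

#: The three features current entomological radar can retrieve.
RADAR_FEATURES: tuple[str, ...] = FEATURE_NAMES[:3]

FEATURE_UNITS: Mapping[str, str] = {
    "mass": "mg",
    "wingbeat_frequency": "Hz",
    "length_to_width_ratio": "",
    "body_length": "mm",
}

#: Name of the label column in tabular files.
LABEL_COLUMN = "species"


class FixtureError(ValueError):
    """Raised when a species-statistics table fails validation."""


def canonical_order(names: Iterable[str]) -> tuple[str, ...]:
    """Return *names* sorted into the canonical feature order.

    Raises ``ValueError`` for names outside the known feature set.
    """
    names = list(names)
    unknown = [n for n in names if n not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s): {unknown!r}")
    return tuple(f for f in FEATURE_NAMES if f in names)


@dataclass(frozen=True)
class FeatureSummary:
    """Printed summary statistics of one feature for one species."""

    mean: float
    std: float
    range_min: float
    range_max: float


@dataclass(frozen=True)
class SpeciesStats:
    """Per-species summary statistics for the four features.

    ``range_suspect`` marks species whose printed min-max range is internally
    implausible (it is stored as printed but excluded from the
    range-contains-mean validation); means and standard deviations, the only
    statistics used for cohort generation, are unaffected.
    """

    label: str
    species_name: str
    family: str
    order: str
    quantity: int
    features: Mapping[str, FeatureSummary] = field(default_factory=dict)
    range_suspect: bool = False

    def feature(self, name: str) -> FeatureSummary:
        try:
            return self.features[name]
        except KeyError:
            raise KeyError(
                f"species {self.label!r} has no statistics for feature {name!r}"
            ) from None

    def validate(self) -> None:
        if self.quantity <= 0:
            raise FixtureError(f"species {self.label!r}: quantity must be positive")
        for name, summ in self.features.items():
            for attr in ("mean", "std", "range_min", "range_max"):
                v = getattr(summ, attr)
                if not np.isfinite(v):
                    raise FixtureError(
                        f"species {self.label!r}, feature {name!r}: {attr} not finite"
                    )
            if summ.std < 0:
                raise FixtureError(
                    f"species {self.label!r}, feature {name!r}: negative std"
                )
            if not self.range_suspect and not (
                summ.range_min <= summ.mean <= summ.range_max
            ):
                raise FixtureError(
                    f"species {self.label!r}, feature {name!r}: mean {summ.mean} "
                    f"outside printed range [{summ.range_min}, {summ.range_max}]"
                )


def _builtin_fixture_path() -> Path:
    return Path(str(importlib.resources.files("dtsvm").joinpath("data/table1.csv")))


def load_species_stats(source: str | Path = "builtin") -> list[SpeciesStats]:
    """Load per-species summary statistics.

    Parameters
    ----------
    source
        ``"builtin"`` for the bundled 23-species fixture, or a path to a CSV
        with the same column layout.

    Returns
    -------
    list of :class:`SpeciesStats`, validated (unique labels, finite cells,
    means inside printed ranges unless the row is flagged ``range_suspect``).
    """
    path = _builtin_fixture_path() if str(source) == "builtin" else Path(source)
    df = pd.read_csv(path, dtype={"label": str})
    required = ["label", "species_name", "family", "order", "quantity", "range_suspect"]
    for feat in FEATURE_NAMES:
        required += [f"{feat}_{s}" for s in ("mean", "std", "min", "max")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FixtureError(f"statistics table {path} is missing column(s): {missing}")

    out: list[SpeciesStats] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        label = row["label"]
        if label in seen:
            raise FixtureError(f"duplicate species label {label!r} (row {i})")
        seen.add(label)
        feats = {}
        for feat in FEATURE_NAMES:
            try:
                feats[feat] = FeatureSummary(
                    mean=float(row[f"{feat}_mean"]),
                    std=float(row[f"{feat}_std"]),
                    range_min=float(row[f"{feat}_min"]),
                    range_max=float(row[f"{feat}_max"]),
                )
            except (TypeError, ValueError) as exc:
                raise FixtureError(
                    f"row {i} (label {label!r}), feature {feat!r}: "
                    f"unparseable statistics cell ({exc})"
                ) from None
        stats = SpeciesStats(
            label=label,
            species_name=str(row["species_name"]),
            family=str(row["family"]),
            order=str(row["order"]),
            quantity=int(row["quantity"]),
            features=feats,
            range_suspect=bool(row["range_suspect"]),
        )
        stats.validate()
        out.append(stats)
    return out


@dataclass
class LabeledDataset:
    """A feature matrix with species labels; the currency of the pipeline.

    ``features`` is an ``(n_samples, n_features)`` float array, ``labels`` a
    length-``n_samples`` array of species codes, and ``feature_names`` names
    the columns in canonical order.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        self.feature_names = tuple(self.feature_names)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D array")
        if self.features.shape[1] != len(self.feature_names):
            raise ValueError(
                f"feature matrix has {self.features.shape[1]} columns but "
                f"{len(self.feature_names)} feature names were given"
            )
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels must be a vector with one entry per sample")
        if self.features.size and not np.isfinite(self.features).all():
            raise ValueError("feature matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def classes(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def column(self, name: str) -> np.ndarray:
        return self.features[:, self.feature_names.index(name)]

    def select_features(self, names: Sequence[str]) -> "LabeledDataset":
        """Project onto a subset of features (kept in canonical order)."""
        names = canonical_order(names)
        missing = [n for n in names if n not in self.feature_names]
        if missing:
            raise ValueError(f"dataset lacks feature(s): {missing}")
        idx = [self.feature_names.index(n) for n in names]
        return LabeledDataset(self.features[:, idx], self.labels.copy(), names)

    def subset(self, index: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[index], self.labels[index], self.feature_names
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df.insert(0, LABEL_COLUMN, self.labels)
        return df


def read_dataset(
    path: str | Path, feature_names: Sequence[str] | None = None
) -> LabeledDataset:
    """Read a labeled feature table from CSV.

    The file must have a ``species`` column plus one column per requested
    feature; columns are reordered to the canonical feature order.  When
    *feature_names* is omitted, all canonical features present in the header
    are used.
    """
    df = pd.read_csv(Path(path), float_precision="round_trip")
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing required column {LABEL_COLUMN!r}")
    if feature_names is None:
        names = canonical_order([c for c in df.columns if c in FEATURE_NAMES])
        if not names:
            raise ValueError(f"{path}: no recognised feature columns in header")
    else:
        names = canonical_order(feature_names)
        missing = [n for n in names if n not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s): {missing}")
    mat = np.empty((len(df), len(names)))
    for j, name in enumerate(names):
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.index[col.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric or missing value in column {name!r} "
                f"at row {int(bad[0])}"
            )
        mat[:, j] = col.to_numpy()
    return LabeledDataset(mat, df[LABEL_COLUMN].astype(str).to_numpy(), names)


def write_dataset(dataset: LabeledDataset, path: str | Path) -> None:
    """Write a labeled feature table as CSV, values at full precision."""
    dataset.to_frame().to_csv(Path(path), index=False)
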