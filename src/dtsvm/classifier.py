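"""Per-node SVM training, cascade prediction and accuracy evaluation.

Each internal node of the DTSVM tree is trained as a two-class RBF SVM on the
standardized samples of the node's species, labeled by which child subtree
their species belongs to.  A test sample is classified by routing it from the
root through successive binary decisions until it reaches a leaf; the leaf's
species is the prediction.

Identification accuracy is per-species recall (correct test samples divided
by the species' test count); the reported mean is the unweighted average over
species, matching balanced test cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.svm import SVC

from .feature_data import LabeledDataset
from .tree_builder import DTSVMTree, TreeNode


@dataclass(frozen=True)
class SVMConfig:
    """Hyperparameters for the per-node binary SVMs.

    Defaults: RBF kernel with ``gamma=0.5`` — a kernel length-scale of one
    standard deviation on standardized features, fine enough to separate
    overlapping species yet smooth enough that samples far from the support
    vectors (possible under heavy measurement noise) are still routed by the
    dominant feature rather than by the decision function's far-field bias —
    and ``C=100``, a hard margin in practice, appropriate because generated
    cohorts carry no label noise.  Unweighted classes by default; set
    ``class_weight="balanced"`` to counteract sample imbalance at deep
    1-vs-many nodes if minority-side node recall matters more than overall
    species recall.
    """

    kernel: str = "rbf"
    C: float = 100.0
    gamma: float | str = 0.5
    class_weight: Optional[str] = None
    cache_size: float = 500.0
    tol: float = 1e-3

    def make(self) -> SVC:
        return SVC(
            kernel=self.kernel,
            C=self.C,
            gamma=self.gamma,
            class_weight=self.class_weight,
            cache_size=self.cache_size,
            tol=self.tol,
        )


def train(
    tree: DTSVMTree,
    training_set: LabeledDataset,
    svm: SVMConfig | None = None,
) -> DTSVMTree:
    """Fit one binary SVM per internal node, in place; returns the tree.

    Every node's classifier is trained only on the training samples of that
    node's species set, labeled 0 for the left subtree and 1 for the right.
    """
    svm = svm or SVMConfig()
    if training_set.feature_names != tree.feature_names:
        raise ValueError(
            f"training features {training_set.feature_names} do not match "
            f"tree features {tree.feature_names}"
        )
    x = training_set.features
    if tree.scaler is not None:
        x = tree.scaler.transform(x)
    labels = training_set.labels
    for node in tree.internal_nodes():
        mask = np.isin(labels, sorted(node.labels))
        side = np.isin(labels[mask], sorted(node.right.labels)).astype(int)
        if side.min() == side.max():
            raise ValueError(
                f"node over {sorted(node.labels)}: training samples cover only "
                "one side of the split (tree/data mismatch)"
            )
        node.classifier = svm.make().fit(x[mask], side)
    return tree


def predict(tree: DTSVMTree, samples: np.ndarray | LabeledDataset) -> np.ndarray:
    """Classify samples by cascading root-to-leaf through the trained tree."""
    x = samples.features if isinstance(samples, LabeledDataset) else np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != len(tree.feature_names):
        raise ValueError(
            f"expected samples with {len(tree.feature_names)} features, "
            f"got shape {x.shape}"
        )
    if tree.scaler is not None:
        x = tree.scaler.transform(x)
    out = np.empty(x.shape[0], dtype=object)

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if idx.size == 0:
            return
        if node.is_leaf:
            out[idx] = node.species
            return
        if node.classifier is None:
            raise ValueError(
                f"node over {sorted(node.labels)} is untrained; call train() first"
            )
        side = node.classifier.predict(x[idx])
        route(node.left, idx[side == 0])
        route(node.right, idx[side == 1])

    route(tree.root, np.arange(x.shape[0]))
    return out.astype(str)


@dataclass
class EvaluationReport:
    """Per-species and mean identification accuracy with confusion matrix."""

    per_species_accuracy: dict[str, float]
    mean_accuracy: float
    confusion: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def to_frame(self, decimals: int | None = None) -> pd.DataFrame:
        """Accuracy table with one row per species plus a 'mean' row."""
        rows = dict(self.per_species_accuracy)
        rows["mean"] = self.mean_accuracy
        df = pd.DataFrame(
            {"species": list(rows), "accuracy": list(rows.values())}
        )
        if decimals is not None:
            df["accuracy"] = df["accuracy"].round(decimals)
        return df

    def min_accuracy(self) -> float:
        return min(self.per_species_accuracy.values())

    def to_csv(self, path: str | Path, decimals: int | None = None) -> None:
        self.to_frame(decimals).to_csv(Path(path), index=False)


def evaluate(
    predictions: np.ndarray,
    truth: np.ndarray,
    metadata: Mapping | None = None,
) -> EvaluationReport:
    """Score predictions against true labels.

    Per-species accuracy is the confusion-matrix diagonal divided by the row
    sum (recall); the mean is unweighted over species.  Predicted labels
    outside the true label set raise.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth must have equal length")
    known = sorted(set(truth.tolist()))
    alien = sorted(set(predictions.tolist()) - set(known))
    if alien:
        raise ValueError(f"predictions contain unknown label(s): {alien}")
    cm = confusion_matrix(truth, predictions, labels=known)
    row_sums = cm.sum(axis=1)
    per_species = {
        label: float(cm[i, i] / row_sums[i]) for i, label in enumerate(known)
    }
    return EvaluationReport(
        per_species_accuracy=per_species,
        mean_accuracy=float(np.mean(list(per_species.values()))),
        confusion=pd.DataFrame(cm, index=known, columns=known),
        metadata=dict(metadata or {}),
    )


def fit_dtsvm(
    training_set: LabeledDataset,
    svm: SVMConfig | None = None,
    *,
    standardize_features: bool = True,
) -> DTSVMTree:
    """Convenience: build the tree from the training set and train all nodes."""
    from .tree_builder import build_tree

    tree = build_tree(training_set, standardize_features=standardize_features)
    return train(tree, training_set, svm)


def save_model(tree: DTSVMTree, path: str | Path) -> None:
    """Serialize a trained tree (topology, scaler, node SVMs) to one archive."""
    joblib.dump(tree, Path(path))


def load_model(path: str | Path) -> DTSVMTree:
    tree = joblib.load(Path(path))
    if not isinstance(tree, DTSVMTree):
        raise ValueError(f"{path} does not contain a DTSVM model")
    return tree
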