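"""Construction of the DTSVM binary tree by separability-driven merging.

An N-class problem is converted into N-1 binary problems arranged in a
binary tree: each internal node will hold a two-class SVM, each leaf is one
species.  The topology is found agglomeratively:

1. compute the ICSF between every pair of current class groups;
2. merge the least-separable pair (smallest ICSF) into one group, recomputing
   its center and spread from the pooled samples;
3. repeat until one group remains.

Read top-down, the resulting dendrogram places the final — most separable —
split at the root, so the easiest decisions are made first and errors do not
cascade through hard splits.  Ties on the minimal ICSF are broken by the
lexicographically smallest merged label string, making construction
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np

from .feature_data import LabeledDataset
from .separability import ClassGroup, Scaler, icsf, make_group, standardize


@dataclass
class TreeNode:
    """A node of the DTSVM tree.

    Internal nodes have two children, the ICSF at which their split was
    formed, and (after training) a binary classifier; leaves carry a single
    species label.
    """

    labels: frozenset[str]
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    merge_icsf: Optional[float] = None
    classifier: Any = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None and self.right is None

    @property
    def species(self) -> str:
        if not self.is_leaf:
            raise ValueError("internal nodes have no single species")
        (label,) = self.labels
        return label

    def __post_init__(self) -> None:
        if (self.left is None) != (self.right is None):
            raise ValueError("internal nodes must have exactly two children")
        if self.is_leaf and len(self.labels) != 1:
            raise ValueError("leaf nodes must carry exactly one label")


@dataclass
class DTSVMTree:
    """Binary tree of (to-be-)trained two-class SVMs over a species set."""

    root: TreeNode
    feature_names: tuple[str, ...]
    scaler: Optional[Scaler] = None

    def leaves(self) -> list[TreeNode]:
        return [n for n in self._walk() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self._walk() if not n.is_leaf]

    def species(self) -> list[str]:
        return sorted(n.species for n in self.leaves())

    def _walk(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            if not node.is_leaf:
                stack.extend([node.left, node.right])
        return out

    def merge_icsf_monotone(self) -> bool:
        """Whether every internal node's merge ICSF dominates its descendants'.

        The greedy merge order usually, but not provably, yields this
        most-separable-at-the-top monotonicity; inversions can occur because
        merging inflates a group's spread.
        """

        def ok(node: TreeNode) -> bool:
            if node.is_leaf:
                return True
            for child in (node.left, node.right):
                if not child.is_leaf and child.merge_icsf > node.merge_icsf:
                    return False
            return ok(node.left) and ok(node.right)

        return ok(self.root)

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.species
            return f"({render(node.left)},{render(node.right)})"

        return render(self.root) + ";"

    def to_json(self) -> str:
        def encode(node: TreeNode) -> dict:
            d: dict = {"labels": sorted(node.labels)}
            if not node.is_leaf:
                d["merge_icsf"] = node.merge_icsf
                d["left"] = encode(node.left)
                d["right"] = encode(node.right)
            return d

        return json.dumps(
            {"feature_names": list(self.feature_names), "root": encode(self.root)},
            indent=2,
        )


def tree_to_text(tree: DTSVMTree) -> str:
    """Newick-style rendering of the tree topology (one leaf per species)."""
    return tree.to_newick()


def parse_newick(text: str):
    """Parse a newick string produced by :func:`tree_to_text`.

    Returns a nested topology of frozensets: a leaf is ``frozenset({label})``
    and an internal node is ``frozenset({left_topology, right_topology})``
    (unordered, so mirrored trees compare equal).
    """
    s = text.strip().rstrip(";")
    pos = 0

    def expect(char: str) -> None:
        nonlocal pos
        if pos >= len(s) or s[pos] != char:
            raise ValueError(f"expected {char!r} at position {pos} in {text!r}")
        pos += 1

    def parse():
        nonlocal pos
        if pos < len(s) and s[pos] == "(":
            pos += 1  # consume '('
            left = parse()
            expect(",")
            right = parse()
            expect(")")
            return frozenset({left, right})
        start = pos
        while pos < len(s) and s[pos] not in "(),":
            pos += 1
        name = s[start:pos].strip()
        if not name:
            raise ValueError(f"empty leaf name at position {start} in {text!r}")
        return frozenset({name})

    out = parse()
    if pos != len(s):
        raise ValueError(f"trailing characters after position {pos} in {text!r}")
    return out


def topology(tree: DTSVMTree):
    """Unordered nested-frozenset topology of *tree* (see :func:`parse_newick`)."""
    return parse_newick(tree.to_newick())


def build_tree(
    training_set: LabeledDataset, *, standardize_features: bool = True
) -> DTSVMTree:
    """Build the (untrained) DTSVM tree from a labeled training set.

    Features are z-scored first by default (the scaler is stored on the tree
    and later applied to test data); set ``standardize_features=False`` for
    strict raw-feature behaviour.
    """
    classes = training_set.classes()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to build a tree")
    for label, count in training_set.class_counts().items():
        if count < 2:
            raise ValueError(f"class {label!r} has fewer than 2 samples")

    if standardize_features:
        data, scaler = standardize(training_set)
    else:
        data, scaler = training_set, None

    # active groups: (tree node, pooled sample row indices, group statistics)
    entries: list[tuple[TreeNode, np.ndarray, ClassGroup]] = []
    for label in classes:
        idx = np.flatnonzero(data.labels == label)
        entries.append(
            (
                TreeNode(labels=frozenset({label})),
                idx,
                make_group({label}, data.features[idx]),
            )
        )

    while len(entries) > 1:
        best: tuple[float, str, int, int] | None = None
        for i in range(len(entries)):
            for j in range(i + 1, len(entries)):
                value = icsf(entries[i][2], entries[j][2])
                key = "".join(sorted(entries[i][2].labels | entries[j][2].labels))
                cand = (value, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        value, _, i, j = best
        node_i, idx_i, grp_i = entries[i]
        node_j, idx_j, grp_j = entries[j]
        # deterministic child order: smaller sorted label string on the left
        if "".join(sorted(grp_i.labels)) > "".join(sorted(grp_j.labels)):
            node_i, idx_i, grp_i, node_j, idx_j, grp_j = (
                node_j, idx_j, grp_j, node_i, idx_i, grp_i,
            )
        idx = np.concatenate([idx_i, idx_j])
        merged = make_group(grp_i.labels | grp_j.labels, data.features[idx])
        node = TreeNode(
            labels=merged.labels, left=node_i, right=node_j, merge_icsf=value
        )
        entries = [e for k, e in enumerate(entries) if k not in (i, j)]
        entries.append((node, idx, merged))

    return DTSVMTree(
        root=entries[0][0], feature_names=training_set.feature_names, scaler=scaler
    )
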