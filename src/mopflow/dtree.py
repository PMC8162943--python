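"""Binary decision tree over fingerprint bits, built from scratch.

Splits are Boolean bit-presence tests chosen greedily to maximize information
gain

    IG(S, A) = H(S) - sum_t (|t| / |S|) * H(t),

where the Shannon entropy of a class split is

    H(S) = - sum_c p(c) * log2 p(c),   0 * log2 0 := 0.

A minimum leaf size (default 2) guards against fitting single analytes.
Tie-breaks and stopping rules are deterministic so that, with feature
subsetting disabled and no row resampling, fitting is fully reproducible
without any seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .dataset import REACTIVE, UNREACTIVE, LabeledDataset

_EPS = 1e-12


def entropy(counts) -> float:
    """Shannon entropy in bits of a per-class count vector."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("entropy of an empty set is undefined")
    p = c[c > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(parent_counts, child_counts_list) -> float:
    """Entropy reduction of splitting ``parent_counts`` into the given subsets."""
    parent = np.asarray(parent_counts, dtype=float)
    children = [np.asarray(c, dtype=float) for c in child_counts_list]
    if not np.array_equal(parent, sum(children)):
        raise ValueError("child counts must sum to parent counts")
    n = parent.sum()
    ig = entropy(parent) - sum(c.sum() / n * entropy(c) for c in children if c.sum() > 0)
    return float(ig)


@dataclass
class TreeConfig:
    """Hyperparameters for one tree.

    ``feature_subset_size``: "all" considers every ever-set column at every
    node; "sqrt" draws ceil(sqrt(pool size)) candidate columns per node
    without replacement; an int draws that many.
    """

    min_leaf_size: int = 2
    max_depth: int | None = None
    feature_subset_size: int | str = "sqrt"

    def __post_init__(self) -> None:
        if self.min_leaf_size < 1:
            raise ValueError("min_leaf_size must be >= 1")


@dataclass
class TreeNode:
    n_reactive: int
    n_unreactive: int
    split_bit: int | None = None
    absent: "TreeNode | None" = None     # child where the bit is 0
    present: "TreeNode | None" = None    # child where the bit is 1

    @property
    def is_leaf(self) -> bool:
        return self.split_bit is None

    @property
    def counts(self) -> tuple[int, int]:
        return self.n_reactive, self.n_unreactive

    @property
    def majority_class(self) -> int:
        # exact ties go to the unreactive (majority/conservative) class
        return REACTIVE if self.n_reactive > self.n_unreactive else UNREACTIVE

    @property
    def leaf_probability(self) -> float:
        """Fraction of reactive training rows at this node."""
        return self.n_reactive / (self.n_reactive + self.n_unreactive)

    def to_dict(self) -> dict:
        d = {"n_reactive": self.n_reactive, "n_unreactive": self.n_unreactive}
        if not self.is_leaf:
            d["split_bit"] = int(self.split_bit)
            d["absent"] = self.absent.to_dict()
            d["present"] = self.present.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(n_reactive=d["n_reactive"], n_unreactive=d["n_unreactive"])
        if "split_bit" in d:
            node.split_bit = d["split_bit"]
            node.absent = cls.from_dict(d["absent"])
            node.present = cls.from_dict(d["present"])
        return node

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TreeNode":
        return cls.from_dict(json.loads(s))


def _node_counts(y: np.ndarray) -> tuple[int, int]:
    pos = int(y.sum())
    return pos, int(y.size - pos)


def best_split(
    X: np.ndarray, y: np.ndarray, candidates: np.ndarray, min_leaf_size: int
) -> tuple[int, float] | None:
    """Highest-IG bit among ``candidates``; ties go to the lowest column index.

    Returns None when no candidate produces a valid (both children >=
    min_leaf_size) split with positive gain.
    """
    n = y.size
    candidates = np.sort(np.asarray(candidates))
    sub = X[:, candidates].astype(float)
    n1 = sub.sum(axis=0)
    pos1 = y.astype(float) @ sub
    n0 = n - n1
    pos0 = y.sum() - pos1
    valid = (n1 >= min_leaf_size) & (n0 >= min_leaf_size)
    if not valid.any():
        return None

    def h(pos, tot):
        p = pos / np.maximum(tot, 1)
        q = 1.0 - p
        t1 = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
        t2 = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
        return -(t1 + t2)

    parent_h = entropy(_node_counts(y))
    ig = parent_h - (n1 / n) * h(pos1, n1) - (n0 / n) * h(pos0, n0)
    ig = np.where(valid, ig, -np.inf)
    best_ig = float(ig.max())
    if best_ig <= _EPS:
        return None
    # ties within float tolerance go to the lowest column index
    best = int(np.flatnonzero(ig >= best_ig - _EPS)[0])
    return int(candidates[best]), float(ig[best])


def fit_tree(
    dataset: LabeledDataset,
    config: TreeConfig | None = None,
    rng: int | np.random.Generator | None = None,
) -> TreeNode:
    """Grow a tree by greedy IG maximization over (optionally subsampled) bits.

    Stops at pure nodes, when no candidate split has positive gain while
    respecting ``min_leaf_size``, or at ``max_depth``.
    """
    if dataset.n == 0:
        raise ValueError("cannot fit a tree on an empty dataset")
    config = config or TreeConfig()
    X = dataset.features.bits
    y = dataset.labels
    pool = dataset.features.set_columns()
    if config.feature_subset_size == "all":
        subset_size = None
    elif config.feature_subset_size == "sqrt":
        subset_size = int(np.ceil(np.sqrt(pool.size))) if pool.size else 0
    else:
        subset_size = int(config.feature_subset_size)
    if subset_size is not None and not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    def grow(idx: np.ndarray, depth: int) -> TreeNode:
        yi = y[idx]
        node = TreeNode(*_node_counts(yi))
        if (
            node.n_reactive == 0
            or node.n_unreactive == 0
            or idx.size < 2 * config.min_leaf_size
            or (config.max_depth is not None and depth >= config.max_depth)
            or pool.size == 0
        ):
            return node
        if subset_size is None:
            candidates = pool
        else:
            candidates = rng.choice(pool, size=min(subset_size, pool.size), replace=False)
        found = best_split(X[idx], yi, candidates, config.min_leaf_size)
        if found is None:
            return node
        bit, _ = found
        mask = X[idx, bit] == 1
        node.split_bit = bit
        node.present = grow(idx[mask], depth + 1)
        node.absent = grow(idx[~mask], depth + 1)
        return node

    return grow(np.arange(dataset.n), 0)


def predict_tree(tree: TreeNode, row: np.ndarray, n_bits: int | None = None) -> tuple[int, float]:
    """Follow bit presence/absence to a leaf; return (class, leaf probability)."""
    row = np.asarray(row).ravel()
    if n_bits is not None and row.size != n_bits:
        raise ValueError(f"feature width {row.size} != training width {n_bits}")
    node = tree
    while not node.is_leaf:
        if node.split_bit >= row.size:
            raise ValueError(
                f"feature width {row.size} too small for split bit {node.split_bit}"
            )
        node = node.present if row[node.split_bit] else node.absent
    return node.majority_class, node.leaf_probability


def tree_depth(tree: TreeNode) -> int:
    if tree.is_leaf:
        return 0
    return 1 + max(tree_depth(tree.absent), tree_depth(tree.present))


def tree_bits(tree: TreeNode) -> dict[int, int]:
    """Map of split bit -> shallowest depth at which this tree tests it."""
    out: dict[int, int] = {}

    def walk(node: TreeNode, depth: int) -> None:
        if node.is_leaf:
            return
        if node.split_bit not in out or depth < out[node.split_bit]:
            out[node.split_bit] = depth
        walk(node.absent, depth + 1)
        walk(node.present, depth + 1)

    walk(tree, 0)
    return out
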