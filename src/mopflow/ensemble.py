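"""Bootstrapped ensembles of fingerprint decision trees.

A single greedy tree on a few dozen analytes is brittle: which functional
group wins a split can hinge on one resampled row or one candidate-feature
draw.  Training B trees (default 10 000) on bootstrap resamples with per-node
random feature subsetting and aggregating their votes gives both a stable
per-analyte reactivity probability (the fraction of trees voting "reactive")
and, just as importantly, per-feature usage frequencies — the raw material
for the chemical reactivity flowchart.

Seeding: one master ``numpy.random.SeedSequence`` spawns one substream per
tree, so tree *i* is identical whether the ensemble has 100 or 10 000 trees.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import REACTIVE, LabeledDataset, bootstrap_resample
from .dtree import TreeConfig, TreeNode, fit_tree, predict_tree, tree_bits


def dataset_digest(dataset: LabeledDataset) -> str:
    h = hashlib.sha256()
    h.update(dataset.features.bits.tobytes())
    h.update(dataset.labels.tobytes())
    h.update(str(dataset.cutoff).encode())
    return h.hexdigest()[:16]


@dataclass
class Ensemble:
    trees: list[TreeNode]
    config: TreeConfig
    seed: int
    row_resampling: bool
    n_bits: int
    radius: int
    cutoff: float
    digest: str
    feature_freq: pd.DataFrame = field(repr=False, default=None)
    # feature_freq columns: bit, overall, root, depth (shallowest-use tallies)

    @property
    def B(self) -> int:
        return len(self.trees)

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "B": self.B,
            "seed": self.seed,
            "row_resampling": self.row_resampling,
            "n_bits": self.n_bits,
            "radius": self.radius,
            "cutoff": self.cutoff,
            "digest": self.digest,
            "min_leaf_size": self.config.min_leaf_size,
            "max_depth": self.config.max_depth,
            "feature_subset_size": self.config.feature_subset_size,
        }
        (directory / "config.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        with open(directory / "trees.jsonl", "w") as fh:
            for t in self.trees:
                fh.write(t.to_json() + "\n")
        self.feature_freq.to_csv(directory / "feature_freq.csv", index=False)

    @classmethod
    def load(cls, directory) -> "Ensemble":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        trees = [
            TreeNode.from_json(line)
            for line in (directory / "trees.jsonl").read_text().splitlines()
            if line
        ]
        config = TreeConfig(
            min_leaf_size=meta["min_leaf_size"],
            max_depth=meta["max_depth"],
            feature_subset_size=meta["feature_subset_size"],
        )
        freq = pd.read_csv(directory / "feature_freq.csv")
        return cls(
            trees=trees,
            config=config,
            seed=meta["seed"],
            row_resampling=meta["row_resampling"],
            n_bits=meta["n_bits"],
            radius=meta["radius"],
            cutoff=meta["cutoff"],
            digest=meta["digest"],
            feature_freq=freq,
        )


def _feature_frequencies(trees: list[TreeNode]) -> pd.DataFrame:
    """Per-bit usage fractions: anywhere in a tree, at the root, per depth."""
    overall: dict[int, int] = {}
    root: dict[int, int] = {}
    per_depth: dict[tuple[int, int], int] = {}
    for t in trees:
        for bit, depth in tree_bits(t).items():
            overall[bit] = overall.get(bit, 0) + 1
            per_depth[(bit, depth)] = per_depth.get((bit, depth), 0) + 1
            if depth == 0:
                root[bit] = root.get(bit, 0) + 1
    B = len(trees)
    rows = []
    for bit in sorted(overall):
        depths = {d: c for (b, d), c in per_depth.items() if b == bit}
        for d in sorted(depths):
            rows.append(
                {
                    "bit": bit,
                    "depth": d,
                    "depth_fraction": depths[d] / B,
                    "overall": overall[bit] / B,
                    "root": root.get(bit, 0) / B,
                }
            )
    return pd.DataFrame(rows, columns=["bit", "depth", "depth_fraction", "overall", "root"])


def fit_ensemble(
    dataset: LabeledDataset,
    B: int = 10_000,
    config: TreeConfig | None = None,
    seed: int = 0,
    row_resampling: bool = True,
) -> Ensemble:
    """Train B bootstrapped trees from a seeded stream of substreams."""
    if B < 1:
        raise ValueError("ensemble size B must be >= 1")
    config = config or TreeConfig()
    streams = np.random.SeedSequence(seed).spawn(B)
    trees = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        data = bootstrap_resample(dataset, rng) if row_resampling else dataset
        trees.append(fit_tree(data, config, rng))
    return Ensemble(
        trees=trees,
        config=config,
        seed=seed,
        row_resampling=row_resampling,
        n_bits=dataset.features.n_bits,
        radius=dataset.features.radius,
        cutoff=dataset.cutoff,
        digest=dataset_digest(dataset),
        feature_freq=_feature_frequencies(trees),
    )


def predict_proba(ensemble: Ensemble, features) -> np.ndarray:
    """Per-row probability of "reactive" = fraction of trees voting reactive."""
    bits = features.bits if hasattr(features, "bits") else np.atleast_2d(features)
    if bits.shape[1] != ensemble.n_bits:
        raise ValueError(
            f"feature width {bits.shape[1]} != training width {ensemble.n_bits}"
        )
    votes = np.zeros(bits.shape[0], dtype=np.int64)
    for tree in ensemble.trees:
        for i in range(bits.shape[0]):
            cls, _ = predict_tree(tree, bits[i])
            votes[i] += cls == REACTIVE
    return votes / ensemble.B


def decide(probabilities, threshold: float = 0.5) -> np.ndarray:
    """Threshold vote fractions into classes; reactive iff probability >= threshold."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(np.int8)


def top_root_bit(ensemble: Ensemble) -> int:
    """The bit most frequently used at tree roots (ties: lowest bit)."""
    freq = ensemble.feature_freq
    roots = freq.drop_duplicates("bit").sort_values(["root", "bit"], ascending=[False, True])
    return int(roots.iloc[0]["bit"])
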