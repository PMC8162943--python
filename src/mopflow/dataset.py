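"""Branching-ratio binarization, gap analysis, and bootstrap resampling.

The binary classifier's positive class ("reactive") is formation of the
diagnostic analyte+MOP adduct; proton transfer and no reaction are pooled as
"unreactive".  The cutoff θ on the branching ratio that separates the classes
is chosen from the gaps in the observed ratio distribution, so a GapReport is
a first-class object here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_io import FeatureMatrix, ReactionRecord, ValidationError

REACTIVE, UNREACTIVE = 1, 0


@dataclass
class LabeledDataset:
    """A FeatureMatrix with binarized reactivity labels.

    ``labels[i] == REACTIVE`` iff ``ratios[i] >= cutoff`` ("70% or greater"
    semantics: the comparison is >=, not >).
    """

    features: FeatureMatrix
    labels: np.ndarray            # int8, 1 = reactive
    cutoff: float
    ratios: np.ndarray
    row_provenance: np.ndarray | None = None   # source-row indices after resampling

    @property
    def n(self) -> int:
        return int(self.labels.shape[0])

    @property
    def class_counts(self) -> tuple[int, int]:
        """(n_reactive, n_unreactive)."""
        n_pos = int(self.labels.sum())
        return n_pos, self.n - n_pos

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.features.row_ids,
                "ratio": self.ratios,
                "label": self.labels,
                "cutoff": self.cutoff,
            }
        )


def binarize(
    records: list[ReactionRecord], features: FeatureMatrix, cutoff: float
) -> LabeledDataset:
    """Label records reactive iff branching ratio >= cutoff (percent)."""
    if not 0.0 < cutoff <= 100.0:
        raise ValidationError(f"cutoff {cutoff} outside (0, 100]")
    missing = [r.name or str(i) for i, r in enumerate(records) if r.branching_ratio is None]
    if missing:
        raise ValidationError(f"records lacking a branching ratio: {missing}")
    ratios = np.array([r.branching_ratio for r in records], dtype=float)
    labels = (ratios >= cutoff).astype(np.int8)
    return LabeledDataset(features=features, labels=labels, cutoff=float(cutoff), ratios=ratios)


@dataclass
class GapReport:
    """Gaps between consecutive distinct branching ratios, widest first."""

    sorted_ratios: np.ndarray                      # ascending, with duplicates
    gaps: list[tuple[float, float, float]] = field(default_factory=list)  # (lower, upper, width)

    @property
    def largest_gap(self) -> tuple[float, float, float]:
        return self.gaps[0]

    @property
    def second_largest_gap(self) -> tuple[float, float, float]:
        return self.gaps[1]


def gap_analysis(records: list[ReactionRecord]) -> GapReport:
    """All inter-ratio gaps sorted by width descending (ties: lower bound first).

    A large empty interval in the ratio distribution is the natural place for
    the binarization cutoff; gap widths over the distinct sorted ratios sum to
    max - min.
    """
    ratios = np.array([r.branching_ratio for r in records], dtype=float)
    distinct = np.unique(ratios)
    if distinct.size < 2:
        raise ValidationError("gap analysis needs >= 2 distinct ratios")
    gaps = [
        (float(lo), float(hi), float(hi - lo))
        for lo, hi in zip(distinct[:-1], distinct[1:])
    ]
    gaps.sort(key=lambda g: (-g[2], g[0]))
    return GapReport(sorted_ratios=np.sort(ratios), gaps=gaps)


def bootstrap_resample(dataset: LabeledDataset, rng: int | np.random.Generator) -> LabeledDataset:
    """Same-size resample with replacement; deterministic given the seed/rng.

    The resampled dataset records row provenance (indices into the source)
    and shares the source's bit_env so interpretation survives resampling.
    """
    if dataset.n == 0:
        raise ValidationError("cannot resample an empty dataset")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    idx = rng.integers(0, dataset.n, size=dataset.n)
    feats = FeatureMatrix(
        bits=dataset.features.bits[idx],
        radius=dataset.features.radius,
        row_ids=[dataset.features.row_ids[i] for i in idx],
        bit_env=dataset.features.bit_env,
    )
    return LabeledDataset(
        features=feats,
        labels=dataset.labels[idx],
        cutoff=dataset.cutoff,
        ratios=dataset.ratios[idx],
        row_provenance=idx,
    )
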