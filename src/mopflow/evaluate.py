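"""Classifier evaluation: confusion counts, Cohen kappa, cutoff x radius
grids, and the proton-affinity baseline / hybrid verification rule.

With an unbalanced class split (8 diagnostic vs 28 non-diagnostic analytes in
the reference training set) raw accuracy is misleading, so models are
compared by the chance-corrected Cohen kappa:

    Po = (TP + TN) / N
    Pe = [(TP + FP)(TP + FN) + (FN + TN)(FP + TN)] / N^2
    k  = (Po - Pe) / (1 - Pe)

kappa = 0 means performance at chance, 1 a perfect classifier.

The proton-affinity (PA) rule — an analyte whose PA exceeds the reagent's may
form the adduct, one whose PA is below it proton-transfers — serves both as a
standalone baseline and as a *hybrid* verification filter: ensemble
predictions are overridden by the PA rule, but only for analytes carrying
fingerprint bits never seen in training (novel functional groups, where the
ensemble is extrapolating).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import REACTIVE, UNREACTIVE, binarize
from .dtree import TreeConfig
from .ensemble import decide, fit_ensemble, predict_proba
from .reaction_io import featurize

logger = logging.getLogger(__name__)

#: DFT-calculated proton affinity of 2-methoxypropene, kcal/mol
MOP_PROTON_AFFINITY = 214.42


@dataclass
class ConfusionMatrix:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0 or self.total < 1:
            raise ValueError("confusion counts must be nonnegative with total >= 1")


def confusion(truth, predicted) -> ConfusionMatrix:
    """Tally TP/FP/TN/FN with "reactive" as the positive class."""
    t = np.asarray(truth, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    return ConfusionMatrix(
        TP=int(((p == REACTIVE) & (t == REACTIVE)).sum()),
        FP=int(((p == REACTIVE) & (t == UNREACTIVE)).sum()),
        TN=int(((p == UNREACTIVE) & (t == UNREACTIVE)).sum()),
        FN=int(((p == UNREACTIVE) & (t == REACTIVE)).sum()),
    )


@dataclass
class EvalReport:
    confusion: ConfusionMatrix
    Po: float
    Pe: float
    kappa: float          # nan when undefined (Pe == 1)
    kappa_undefined: bool
    table: pd.DataFrame | None = None   # per-row: id, truth, probability, prediction


def kappa(cm: ConfusionMatrix) -> EvalReport:
    """Accuracy, chance probability and Cohen kappa from confusion counts."""
    n = cm.total
    po = (cm.TP + cm.TN) / n
    pe = ((cm.TP + cm.FP) * (cm.TP + cm.FN) + (cm.FN + cm.TN) * (cm.FP + cm.TN)) / n**2
    undefined = pe >= 1.0 - 1e-15
    k = float("nan") if undefined else (po - pe) / (1.0 - pe)
    return EvalReport(confusion=cm, Po=po, Pe=pe, kappa=k, kappa_undefined=undefined)


def evaluate_predictions(truth, predicted, ids=None, probabilities=None) -> EvalReport:
    report = kappa(confusion(truth, predicted))
    if ids is not None:
        report.table = pd.DataFrame(
            {
                "id": ids,
                "truth": np.asarray(truth, dtype=int),
                "probability": probabilities,
                "prediction": np.asarray(predicted, dtype=int),
            }
        )
    return report


#: cutoffs compared in the reference study; 80 is omitted because it labels
#: the training set identically to 70
DEFAULT_CUTOFFS = (10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 90.0)
DEFAULT_RADII = (1, 2, 3)


def grid_scan(
    train_records,
    test_records,
    test_truth,
    cutoffs=DEFAULT_CUTOFFS,
    radii=DEFAULT_RADII,
    B: int = 10_000,
    seed: int = 0,
    n_bits: int = 2048,
    config: TreeConfig | None = None,
    vote_threshold: float = 0.5,
) -> pd.DataFrame:
    """Train and evaluate one ensemble per (cutoff, radius) cell.

    Cells whose cutoff labels the training set single-class are skipped with
    a warning.  Fully reproducible for a fixed seed: the cell seed is derived
    from (seed, cutoff, radius), so adding cells does not perturb others.
    """
    truth = np.asarray(test_truth, dtype=int)
    rows = []
    for radius in radii:
        train_fm = featurize(train_records, radius=radius, n_bits=n_bits)
        test_fm = featurize(test_records, radius=radius, n_bits=n_bits)
        for cutoff in cutoffs:
            dataset = binarize(train_records, train_fm, cutoff)
            n_pos, n_neg = dataset.class_counts
            if n_pos == 0 or n_neg == 0:
                warnings.warn(
                    f"cutoff {cutoff} yields a single-class training set; skipped",
                    stacklevel=2,
                )
                continue
            cell_seed = int(
                np.random.SeedSequence([seed, int(cutoff * 10), radius]).generate_state(1)[0]
                % (2**31)
            )
            ens = fit_ensemble(dataset, B=B, config=config, seed=cell_seed)
            proba = predict_proba(ens, test_fm)
            report = kappa(confusion(truth, decide(proba, vote_threshold)))
            cm = report.confusion
            rows.append(
                {
                    "cutoff": cutoff,
                    "radius": radius,
                    "TP": cm.TP,
                    "FP": cm.FP,
                    "TN": cm.TN,
                    "FN": cm.FN,
                    "Po": report.Po,
                    "Pe": report.Pe,
                    "kappa": report.kappa,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PABaselineConfig:
    """Configuration for the proton-affinity rule.

    ``reagent_pa`` defaults to the DFT-calculated MOP value.  In hybrid mode
    the rule only overrides ensemble predictions for analytes flagged by the
    novel-group policy (fingerprint bits absent from the training matrix).
    """

    reagent_pa: float = MOP_PROTON_AFFINITY
    mode: str = "standalone"          # "standalone" | "hybrid-filter"

    def __post_init__(self) -> None:
        if self.reagent_pa <= 0:
            raise ValueError("reagent_pa must be positive")
        if self.mode not in {"standalone", "hybrid-filter"}:
            raise ValueError(f"unknown PA baseline mode {self.mode!r}")


def pa_baseline(pas, config: PABaselineConfig | None = None) -> np.ndarray:
    """Standalone PA classifier: reactive iff PA strictly exceeds the reagent's.

    Ties score unreactive: adduct formation is only *possible* above the
    reagent PA, and sub-0.1 kcal/mol orderings carry no real significance.
    """
    config = config or PABaselineConfig()
    pa = np.asarray(pas, dtype=float)
    if np.isnan(pa).any():
        missing = list(np.flatnonzero(np.isnan(pa)))
        raise ValueError(f"proton affinity missing for rows {missing}")
    return (pa > config.reagent_pa).astype(np.int8)


def novel_bit_rows(train_bits: np.ndarray, query_bits: np.ndarray) -> np.ndarray:
    """Boolean mask of query rows carrying >= 1 bit never set in training."""
    seen = train_bits.any(axis=0)
    return (query_bits & ~seen).any(axis=1)


def hybrid_pa_filter(
    predictions,
    pas,
    novel_mask,
    reagent_pa: float = MOP_PROTON_AFFINITY,
) -> np.ndarray:
    """Override ensemble predictions with the PA rule on novel-group rows.

    For rows where ``novel_mask`` is True the prediction becomes the PA
    verdict (reactive iff PA > reagent_pa); other rows pass through.  PA is
    only required where the mask applies.
    """
    pred = np.asarray(predictions, dtype=np.int8).copy()
    mask = np.asarray(novel_mask, dtype=bool)
    pa = np.asarray(pas, dtype=float)
    missing = np.flatnonzero(mask & np.isnan(pa))
    if missing.size:
        raise ValueError(
            f"proton affinity required but missing for novel-group rows {list(missing)}"
        )
    pred[mask] = (pa[mask] > reagent_pa).astype(np.int8)
    return pred
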