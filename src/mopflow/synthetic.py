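"""Synthetic libraries with planted substructure rules, plus bundled fixtures.

Every stage of the pipeline is testable without external data via two routes:

* :func:`generate_library` emits molecule libraries in which a planted
  substructure (by default an aliphatic sulfoxide, the motif that dominates
  MOP adduct formation) determines the branching ratio up to Gaussian noise
  and a small label-flip probability.  A correct pipeline must recover the
  planted rule as its top feature and flowchart root.

* bundled reference fixtures: the 13-compound blind-test table (outcomes,
  per-cutoff vote fractions, proton affinities), named compounds with
  best-effort SMILES, and a clearly-labelled *synthetic* stand-in for the
  36-analyte training ratio distribution.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from rdkit import Chem

from .reaction_io import FeatureMatrix, ReactionRecord

#: SMARTS for the default planted motif: sulfoxide with >=1 aliphatic carbon
ALIPHATIC_SULFOXIDE = "[CX4][SX3](=O)[#6]"


@dataclass
class PlantedRule:
    """Generative rule: pattern presence sets the branching-ratio regime.

    Defaults emulate the observed reactivity landscape: pattern-bearing
    analytes cluster near 90% branching ratio, the rest near 5%, with 5 s.d.
    of measurement-scale noise and a 5% chance of drawing from the wrong
    regime (label noise).
    """

    pattern: str = ALIPHATIC_SULFOXIDE
    base_ratio_present: float = 90.0
    base_ratio_absent: float = 5.0
    noise_sd: float = 5.0
    flip_prob: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValueError("flip_prob must lie in [0, 0.5)")
        if Chem.MolFromSmarts(self.pattern) is None:
            raise ValueError(f"unparsable SMARTS pattern {self.pattern!r}")

    @property
    def query(self) -> Chem.Mol:
        return Chem.MolFromSmarts(self.pattern)


# attachment grammar: alkyl/aryl scaffolds x decorating groups
_SCAFFOLDS = ["C", "CC", "CCC", "CCCC", "CCCCC", "CC(C)", "CC(C)C", "C1CCCCC1"]
_PRESENT_GROUPS = ["S(C)=O", "S(CC)=O", "CS(C)=O"]           # aliphatic sulfoxides
_ABSENT_GROUPS = [
    "S(C)(=O)=O",        # sulfone
    "[N+](=O)[O-]",      # nitro
    "O",                 # alcohol
    "N",                 # amine
    "C(C)=O",            # ketone
    "OC",                # ether
    "C#N",               # nitrile
    "c1ccccc1",          # aryl
]


def generate_library(
    n: int, rule: PlantedRule | None = None, seed: int = 0
) -> list[ReactionRecord]:
    """Generate ``n`` records whose ratios follow the planted rule.

    Roughly half the molecules carry the planted pattern.  Deterministic for
    a fixed seed; all emitted SMILES are valid and canonicalized.
    """
    if n < 2:
        raise ValueError("library size must be >= 2")
    rule = rule or PlantedRule()
    query = rule.query
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        wants_pattern = bool(rng.integers(0, 2))
        pool = _PRESENT_GROUPS if wants_pattern else _ABSENT_GROUPS
        while True:
            smiles = str(rng.choice(_SCAFFOLDS)) + str(rng.choice(pool))
            mol = Chem.MolFromSmiles(smiles)
            if mol is not None and mol.HasSubstructMatch(query) == wants_pattern:
                break
        reactive = wants_pattern ^ (rng.random() < rule.flip_prob)
        mean = rule.base_ratio_present if reactive else rule.base_ratio_absent
        ratio = float(np.clip(rng.normal(mean, rule.noise_sd), 0.0, 100.0))
        records.append(
            ReactionRecord(
                analyte_smiles=smiles, branching_ratio=ratio, name=f"syn{i}"
            )
        )
    return records


def rule_match_vector(records: list[ReactionRecord], rule: PlantedRule) -> np.ndarray:
    """Per-record presence of the planted pattern (structure-level truth)."""
    query = rule.query
    return np.array(
        [int(r.mol.HasSubstructMatch(query)) for r in records], dtype=np.int8
    )


def planted_columns(matrix: FeatureMatrix, match: np.ndarray) -> list[int]:
    """Fingerprint columns whose presence exactly tracks the planted pattern."""
    match = np.asarray(match, dtype=matrix.bits.dtype)
    return [int(c) for c in matrix.set_columns() if np.array_equal(matrix.bits[:, c], match)]


def _read_data(name: str) -> pd.DataFrame:
    # '#' only comments out whole lines: SMILES legitimately contain '#'
    text = resources.files("mopflow.data").joinpath(name).read_text()
    body = "\n".join(l for l in text.splitlines() if not l.startswith("#"))
    return pd.read_csv(io.StringIO(body))


def blind_test_table() -> pd.DataFrame:
    """The 13-analyte prospective blind-test table.

    Columns: id; outcome (Yes/No = diagnostic adduct observed); p20..p70
    (ensemble vote fractions in percent for six branching-ratio cutoffs at
    fingerprint radius 1); proton_affinity (kcal/mol, DFT);
    pa_above_reagent (PA strictly above the reagent's 214.42); novel_nitro
    (nitro compound absent from the training chemistry — the hybrid PA
    filter's scope).
    """
    df = _read_data("blind_test.csv")
    df["truth"] = (df["outcome"] == "Yes").astype(np.int8)
    return df


def named_compounds() -> pd.DataFrame:
    """Named training/test compounds with best-effort SMILES."""
    return _read_data("named_compounds.csv")


def synthetic_training_table() -> list[ReactionRecord]:
    """SYNTHETIC 36-analyte training stand-in (see data-file header).

    Matches the published distributional facts about the real training table
    (size, gap structure, class splits at the candidate cutoffs, named
    compounds placed in their stated ratio bands) while individual ratios and
    most structures are invented.
    """
    df = _read_data("synthetic_training_ratios.csv")
    return [
        ReactionRecord(
            analyte_smiles=row.smiles,
            branching_ratio=float(row.branching_ratio),
            name=row.name_,
        )
        for row in df.rename(columns={"name": "name_"}).itertuples(index=False)
    ]


def reference_fixtures() -> dict:
    """Bundle of all built-in fixtures (see the individual accessors)."""
    return {
        "blind_test": blind_test_table(),
        "named_compounds": named_compounds(),
        "synthetic_training": synthetic_training_table(),
    }
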