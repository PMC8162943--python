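"""Reaction-table parsing and Morgan-fingerprint featurization.

The unit of data is one ion-molecule reaction: a protonated analyte reacting
with 2-methoxypropene (MOP) in an ion trap, annotated with the measured
diagnostic-product branching ratio (the abundance of the stable analyte+MOP
adduct divided by the abundance of all product ions, in percent).

Analytes are featurized as binary Morgan (ECFP-like) fingerprints of the
*neutral* analyte structure.  Full reaction-SMILES input is accepted, but the
analyte is recovered from the reactant side and deprotonated before
fingerprinting: the MOP reactant and the adduct product are constant across
records and would contribute no information gain, while the interpretable
features of interest are all analyte substructures.  Every set bit is mapped
back to the atom environment(s) that generated it so downstream models stay
chemically readable.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

logger = logging.getLogger(__name__)

#: canonical SMILES of 2-methoxypropene, the neutral reagent
MOP_SMILES = "C=C(C)OC"


class ValidationError(ValueError):
    """Raised when an input table or structure fails validation."""


@dataclass
class ReactionRecord:
    """One analyte's reaction with MOP.

    Parameters
    ----------
    analyte_smiles:
        Structure of the neutral analyte; canonicalized on construction.
    branching_ratio:
        Diagnostic-product branching ratio in percent, in [0, 100].  ``None``
        only for prediction-only queries.
    name:
        Free-text identifier.
    proton_affinity:
        Optional PA in kcal/mol (computed externally; consumed as data).
    reaction_smiles:
        Optional full reaction-SMILES the record was derived from.
    """

    analyte_smiles: str
    branching_ratio: float | None = None
    name: str = ""
    proton_affinity: float | None = None
    reaction_smiles: str | None = None

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.analyte_smiles)
        if mol is None or mol.GetNumHeavyAtoms() < 1:
            raise ValidationError(
                f"record {self.name!r}: unparsable analyte SMILES "
                f"{self.analyte_smiles!r}"
            )
        self.analyte_smiles = Chem.MolToSmiles(mol)
        if self.branching_ratio is not None:
            r = float(self.branching_ratio)
            if not 0.0 <= r <= 100.0:
                raise ValidationError(
                    f"record {self.name!r}: branching ratio {r} outside [0, 100]"
                )
            self.branching_ratio = r

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.analyte_smiles)


def deprotonate(mol: Chem.Mol) -> Chem.Mol:
    """Remove one proton from the first protonated (positive, H-bearing) atom.

    Returns the molecule unchanged when no such site exists (already neutral).
    Zwitterionic charges without attached hydrogens (e.g. nitro, N-oxide) are
    left intact.
    """
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        if atom.GetFormalCharge() > 0 and atom.GetTotalNumHs() > 0:
            atom.SetFormalCharge(atom.GetFormalCharge() - 1)
            if atom.GetNumExplicitHs() > 0:
                atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
            break
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return out


def analyte_from_reaction(reaction_smiles: str) -> str:
    """Extract the neutral analyte SMILES from a reaction-SMILES string.

    The reactant side is split on '.'; the MOP reagent is discarded and the
    remaining (protonated) species is deprotonated.
    """
    reactant_side = reaction_smiles.split(">")[0]
    candidates = []
    for part in reactant_side.split("."):
        mol = Chem.MolFromSmiles(part)
        if mol is None:
            raise ValidationError(f"unparsable reactant {part!r} in reaction SMILES")
        if Chem.MolToSmiles(mol) == MOP_SMILES:
            continue
        candidates.append(mol)
    if len(candidates) != 1:
        raise ValidationError(
            f"expected exactly one non-MOP reactant, found {len(candidates)} "
            f"in {reaction_smiles!r}"
        )
    return Chem.MolToSmiles(deprotonate(candidates[0]))


def _record_from_structure(structure: str, **kw) -> ReactionRecord:
    if ">" in structure:
        return ReactionRecord(
            analyte_smiles=analyte_from_reaction(structure),
            reaction_smiles=structure,
            **kw,
        )
    return ReactionRecord(analyte_smiles=structure, **kw)


def read_reaction_table(path, format: str | None = None) -> list[ReactionRecord]:
    """Read reaction records from a delimited table or a .smi file.

    Delimited tables need a ``smiles`` column; ``branching_ratio``, ``name``
    and ``proton_affinity`` are optional.  ``.smi`` files hold one
    whitespace-separated ``structure name`` pair per line.  Structures may be
    plain SMILES or full reaction-SMILES (``reactants>>products``).

    Invalid rows (unparsable structure, ratio outside [0, 100]) raise
    :class:`ValidationError` naming every offending row.
    """
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    if format not in {"tsv", "csv", "smi"}:
        raise ValidationError(f"unknown table format {format!r}")

    rows: list[dict]
    if format == "smi":
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split(None, 1)
                rows.append(
                    {"smiles": parts[0], "name": parts[1] if len(parts) > 1 else ""}
                )
    else:
        df = pd.read_csv(path, sep="\t" if format == "tsv" else ",")
        if "smiles" not in df.columns:
            raise ValidationError(f"{path}: required column 'smiles' is absent")
        rows = df.to_dict("records")

    if not rows:
        warnings.warn(f"{path}: empty reaction table", stacklevel=2)
        return []

    records: list[ReactionRecord] = []
    problems: list[str] = []
    for i, row in enumerate(rows):
        kw = {}
        for col in ("branching_ratio", "proton_affinity"):
            val = row.get(col)
            if val is not None and not (isinstance(val, float) and np.isnan(val)):
                kw[col] = float(val)
        name = row.get("name")
        kw["name"] = "" if name is None or (isinstance(name, float) and np.isnan(name)) else str(name)
        try:
            records.append(_record_from_structure(str(row["smiles"]), **kw))
        except ValidationError as exc:
            problems.append(f"row {i + 1}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    return records


def write_reaction_table(records: list[ReactionRecord], path, format: str | None = None) -> None:
    """Serialize records; inverse of :func:`read_reaction_table`."""
    path = str(path)
    if format is None:
        format = path.rsplit(".", 1)[-1].lower()
    if format == "smi":
        with open(path, "w") as fh:
            for r in records:
                fh.write(f"{r.analyte_smiles} {r.name}\n")
        return
    df = pd.DataFrame(
        {
            "smiles": [r.analyte_smiles for r in records],
            "branching_ratio": [r.branching_ratio for r in records],
            "name": [r.name for r in records],
            "proton_affinity": [r.proton_affinity for r in records],
        }
    )
    df.to_csv(path, sep="\t" if format == "tsv" else ",", index=False)


@dataclass
class BitEnvironment:
    """Substructure interpretation of one fingerprint column."""

    patterns: list[str]               # canonical fragment SMILES, one per distinct environment
    smarts: str                       # query pattern for the representative environment
    example: tuple[str, int, int]     # (row id, center atom index, radius)
    collision: bool = False           # >1 distinct environment hashes here

    def to_dict(self) -> dict:
        return {
            "patterns": self.patterns,
            "smarts": self.smarts,
            "example": list(self.example),
            "collision": self.collision,
        }


@dataclass
class FeatureMatrix:
    """Binary fingerprint matrix (analytes x bits) with bit interpretation."""

    bits: np.ndarray                  # uint8, shape (n_records, n_bits)
    radius: int
    row_ids: list[str]
    bit_env: dict[int, BitEnvironment] = field(default_factory=dict)

    @property
    def n_bits(self) -> int:
        return int(self.bits.shape[1])

    def set_columns(self) -> np.ndarray:
        """Columns set in at least one row, ascending."""
        return np.flatnonzero(self.bits.any(axis=0))

    def save(self, matrix_path, env_path) -> None:
        df = pd.DataFrame(self.bits, index=self.row_ids)
        df.to_csv(matrix_path, sep="\t", header=False)
        meta = {
            "radius": self.radius,
            "n_bits": self.n_bits,
            "bit_env": {str(c): e.to_dict() for c, e in sorted(self.bit_env.items())},
        }
        with open(env_path, "w") as fh:
            json.dump(meta, fh, indent=1, sort_keys=True)


def load_feature_matrix(matrix_path, env_path) -> FeatureMatrix:
    """Inverse of :meth:`FeatureMatrix.save`."""
    df = pd.read_csv(matrix_path, sep="\t", header=None, index_col=0)
    with open(env_path) as fh:
        meta = json.load(fh)
    bit_env = {
        int(c): BitEnvironment(
            patterns=d["patterns"],
            smarts=d["smarts"],
            example=tuple(d["example"]),
            collision=d["collision"],
        )
        for c, d in meta["bit_env"].items()
    }
    return FeatureMatrix(
        bits=df.to_numpy(dtype=np.uint8),
        radius=meta["radius"],
        row_ids=[str(i) for i in df.index],
        bit_env=bit_env,
    )


def _environment_fragment(mol: Chem.Mol, atom: int, radius: int) -> tuple[str, str]:
    """(canonical fragment SMILES, SMARTS) for one circular atom environment."""
    if radius == 0:
        frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[atom], canonical=True)
        smarts = Chem.MolFragmentToSmarts(mol, atomsToUse=[atom])
        return frag, smarts
    bond_path = Chem.FindAtomEnvironmentOfRadiusN(mol, radius, atom)
    amap: dict[int, int] = {}
    submol = Chem.PathToSubmol(mol, bond_path, atomMap=amap)
    frag = Chem.MolToSmiles(submol, canonical=True)
    smarts = Chem.MolToSmarts(submol)
    return frag, smarts


def featurize(
    records: list[ReactionRecord], radius: int = 1, n_bits: int = 2048
) -> FeatureMatrix:
    """Morgan-fingerprint a list of records into a binary FeatureMatrix.

    Bits are presence/absence of hashed circular atom environments of radius
    0..``radius`` on the neutral analyte.  ``bit_env`` maps every set column
    to its generating environment(s); a column reached by more than one
    distinct environment is flagged as a bit collision.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 1:
        raise ValueError("n_bits must be >= 1")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    bits = np.zeros((len(records), n_bits), dtype=np.uint8)
    env_frags: dict[int, dict[str, tuple[str, tuple[str, int, int]]]] = {}
    for i, rec in enumerate(records):
        mol = rec.mol
        if mol is None:
            raise ValidationError(f"record {rec.name!r}: unparsable structure")
        ao = rdFingerprintGenerator.AdditionalOutput()
        ao.AllocateBitInfoMap()
        fp = gen.GetFingerprint(mol, additionalOutput=ao)
        cols = list(fp.GetOnBits())
        bits[i, cols] = 1
        row_id = rec.name or str(i)
        for col, sites in ao.GetBitInfoMap().items():
            store = env_frags.setdefault(col, {})
            for atom, rad in sites:
                frag, smarts = _environment_fragment(mol, atom, rad)
                store.setdefault(frag, (smarts, (row_id, atom, rad)))
    bit_env = {}
    for col, store in env_frags.items():
        frags = sorted(store)
        rep_smarts, example = store[frags[0]]
        bit_env[col] = BitEnvironment(
            patterns=frags,
            smarts=rep_smarts,
            example=example,
            collision=len(frags) > 1,
        )
    row_ids = [r.name or str(i) for i, r in enumerate(records)]
    return FeatureMatrix(bits=bits, radius=radius, row_ids=row_ids, bit_env=bit_env)


def describe_bit(matrix: FeatureMatrix, column: int) -> BitEnvironment:
    """Interpret one fingerprint column; errors if the column is never set."""
    if column not in matrix.bit_env:
        raise KeyError(f"column {column} is never set in this matrix")
    env = matrix.bit_env[column]
    if env.collision:
        logger.info(
            "bit %d is a collision of %d environments: %s",
            column, len(env.patterns), env.patterns,
        )
    return env
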