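"""Chemical reactivity flowcharts: readable distillation of a tree ensemble.

A flowchart is an ordered sequence of Boolean substructure checks ("does the
analyte contain an aliphatic sulfoxide?") ending in reactive/unreactive
assignments — the object a chemist reads instead of 10 000 trees.

Construction is greedy conditional-frequency distillation.  The state is a
partial assignment of fingerprint bits (the answers given so far).  Every
tree is consulted under that assignment: following known bits, a tree either
reaches a leaf (a decided vote) or stops at a node testing an unknown bit
(its "next question"; its vote is then the training-count majority at that
node).  If the reactive vote fraction clears the purity threshold, the branch
terminates in that class; otherwise the bit most trees ask next becomes the
next check and both answers are recursed on.  A node's ``support`` is the
fraction of trees still undecided when the check is made, which shrinks
monotonically along every path.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .dataset import REACTIVE, UNREACTIVE
from .dtree import TreeNode
from .ensemble import Ensemble

CLASS_NAMES = {REACTIVE: "reactive", UNREACTIVE: "unreactive"}

# small alias dictionary for naming common environments in chart labels
_ALIASES = [
    ("nitro", "[NX3](~[OX1])~[OX1]"),
    ("N-oxide", "[#7+]-[O-]"),
    ("hydroxylamino", "[NX3]-[OX2H1]"),
    ("sulfoxide", "[#16X3]=[OX1]"),
    ("carbonyl", "[CX3]=[OX1]"),
]


def alias_for(fragment: str) -> str | None:
    """Free-text name for an environment fragment, if a known group matches."""
    mol = Chem.MolFromSmiles(fragment, sanitize=False)
    if mol is None:
        return None
    try:
        Chem.SanitizeMol(
            mol, Chem.SanitizeFlags.SANITIZE_ALL ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
        )
    except Exception:
        return None
    for name, smarts in _ALIASES:
        patt = Chem.MolFromSmarts(smarts)
        if patt is not None and mol.HasSubstructMatch(patt):
            return name
    return None


@dataclass
class ChartNode:
    """Either a Boolean substructure check or a terminal class assignment."""

    kind: str                      # "check" | "class"
    bit: int | None = None
    description: str = ""
    support: float = 1.0           # fraction of trees undecided at this check
    asked_fraction: float = 0.0    # fraction of trees whose next question is this bit
    yes: "ChartNode | None" = None
    no: "ChartNode | None" = None
    label: int | None = None       # class nodes only
    probability: float | None = None

    def to_dict(self) -> dict:
        if self.kind == "class":
            return {
                "kind": "class",
                "label": int(self.label),
                "probability": self.probability,
            }
        return {
            "kind": "check",
            "bit": int(self.bit),
            "description": self.description,
            "support": self.support,
            "asked_fraction": self.asked_fraction,
            "yes": self.yes.to_dict(),
            "no": self.no.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChartNode":
        if d["kind"] == "class":
            return cls(kind="class", label=d["label"], probability=d["probability"])
        return cls(
            kind="check",
            bit=d["bit"],
            description=d["description"],
            support=d["support"],
            asked_fraction=d["asked_fraction"],
            yes=cls.from_dict(d["yes"]),
            no=cls.from_dict(d["no"]),
        )


@dataclass
class Flowchart:
    root: ChartNode
    n_bits: int
    provenance: dict = field(default_factory=dict)  # ensemble digest, cutoff, radius

    def check_bits(self) -> list[int]:
        """All check bits in preorder (yes branch before no branch)."""
        out: list[int] = []

        def walk(node: ChartNode) -> None:
            if node.kind == "check":
                out.append(node.bit)
                walk(node.yes)
                walk(node.no)

        walk(self.root)
        return out

    def spine(self) -> list[int]:
        """Check bits along the primary path (follow the branch that keeps
        asking questions; the no branch when both do)."""
        out: list[int] = []
        node = self.root
        while node.kind == "check":
            out.append(node.bit)
            if node.no.kind == "check":
                node = node.no
            else:
                node = node.yes
        return out

    def predict(self, row: np.ndarray) -> int:
        """Execute the flowchart as a classifier on one fingerprint row."""
        node = self.root
        while node.kind == "check":
            node = node.yes if row[node.bit] else node.no
        return node.label

    def to_dict(self) -> dict:
        return {
            "root": self.root.to_dict(),
            "n_bits": self.n_bits,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Flowchart":
        return cls(
            root=ChartNode.from_dict(d["root"]),
            n_bits=d["n_bits"],
            provenance=d["provenance"],
        )


def _tree_status(tree: TreeNode, assign: dict[int, int]) -> tuple[int, int | None]:
    """(vote, next unknown bit or None) for one tree under a partial assignment.

    At a node testing an unknown bit the vote falls back to that node's
    training-count majority.
    """
    node = tree
    while not node.is_leaf:
        b = node.split_bit
        if b in assign:
            node = node.present if assign[b] else node.absent
        else:
            return node.majority_class, b
    return node.majority_class, None


def describe_column(features, bit: int) -> str:
    env = getattr(features, "bit_env", {}).get(bit)
    if env is None:
        return f"bit {bit}"
    frag = env.patterns[0]
    name = alias_for(frag)
    label = f"{frag}" if name is None else f"{name} ({frag})"
    if env.collision:
        label += " [collision]"
    return label


def build_flowchart(
    ensemble: Ensemble,
    dataset,
    max_depth: int = 8,
    purity: float = 0.9,
) -> Flowchart:
    """Distill the ensemble into a flowchart of substructure checks.

    ``dataset`` is the training :class:`~mopflow.dataset.LabeledDataset` (or
    any object with ``features``/``labels``); its bit -> substructure map
    labels the nodes, and its rows anchor the termination rule.

    At each partial assignment the next check is the bit most trees ask next
    (the conditional feature frequency).  A branch terminates in a class when
    the training rows consistent with the answers so far are at least
    ``purity`` one class — the same criterion a chemist applies when reading
    the chart: once "no sulfoxide, no N-oxide, ..." leaves only unreactive
    training analytes, the branch is an assignment, not another question.
    """
    B = ensemble.B
    features = dataset.features
    bits = features.bits
    labels = np.asarray(dataset.labels)

    def grow(assign: dict[int, int], depth: int) -> ChartNode:
        votes = np.empty(B, dtype=np.int8)
        decided = np.zeros(B, dtype=bool)
        asked: Counter = Counter()
        for i, tree in enumerate(ensemble.trees):
            vote, nxt = _tree_status(tree, assign)
            votes[i] = vote
            if nxt is None:
                decided[i] = True
            else:
                asked[nxt] += 1
        mask = np.ones(bits.shape[0], dtype=bool)
        for b, v in assign.items():
            mask &= bits[:, b] == v
        rows = labels[mask]
        if rows.size:
            frac = float(rows.mean())
        else:  # no training row matches: fall back to the trees' votes
            frac = float((votes == REACTIVE).mean())
        pure = frac >= purity or frac <= 1.0 - purity
        # only bits that actually separate the consistent rows are askable;
        # bits inducing the same row partition are one functional-group check
        # (distinct fingerprint environments of the same substructure), pooled
        # under the lowest column index so retrained charts stay comparable
        groups: dict[tuple, list[int]] = {}
        for b, c in asked.items():
            col = bits[mask, b]
            if rows.size and 0 < int(col.sum()) < rows.size:
                groups.setdefault(tuple(col), []).append(b)
        askable = {
            min(members): sum(asked[b] for b in members)
            for members in groups.values()
        }
        if depth >= max_depth or pure or not askable:
            label = REACTIVE if frac >= 0.5 else UNREACTIVE
            return ChartNode(kind="class", label=label, probability=frac)
        # most-asked group; ties broken toward the lowest column index
        bit, count = min(askable.items(), key=lambda kv: (-kv[1], kv[0]))
        return ChartNode(
            kind="check",
            bit=bit,
            description=describe_column(features, bit),
            support=float((~decided).mean()),
            asked_fraction=count / B,
            yes=grow({**assign, bit: 1}, depth + 1),
            no=grow({**assign, bit: 0}, depth + 1),
        )

    root = grow({}, 0)
    return Flowchart(
        root=root,
        n_bits=ensemble.n_bits,
        provenance={
            "digest": ensemble.digest,
            "cutoff": ensemble.cutoff,
            "radius": ensemble.radius,
            "B": B,
        },
    )


@dataclass
class FlowchartDiff:
    shared_prefix: int
    added: list[int]
    removed: list[int]
    class_changes: list[str]
    same_root: bool

    @property
    def is_empty(self) -> bool:
        return not self.added and not self.removed and not self.class_changes


def compare_flowcharts(a: Flowchart, b: Flowchart) -> FlowchartDiff:
    """Structural diff: shared check prefix, added/removed checks, class flips."""
    if a.n_bits != b.n_bits:
        raise ValueError("flowcharts were built over different feature spaces")
    spine_a, spine_b = a.spine(), b.spine()
    shared = 0
    for x, y in zip(spine_a, spine_b):
        if x != y:
            break
        shared += 1
    bits_a, bits_b = set(a.check_bits()), set(b.check_bits())
    changes: list[str] = []

    def terminal_class(chart: Flowchart, bit: int, answer: str) -> int | None:
        node = chart.root
        while node.kind == "check":
            if node.bit == bit:
                nxt = node.yes if answer == "yes" else node.no
                return nxt.label if nxt.kind == "class" else None
            node = node.no if node.no.kind == "check" else node.yes
        return None

    for bit in [s for s in spine_a[:shared]]:
        for answer in ("yes", "no"):
            ca, cb = terminal_class(a, bit, answer), terminal_class(b, bit, answer)
            if ca is not None and cb is not None and ca != cb:
                changes.append(
                    f"check bit {bit} ({answer}): {CLASS_NAMES[ca]} -> {CLASS_NAMES[cb]}"
                )
    return FlowchartDiff(
        shared_prefix=shared,
        added=sorted(bits_b - bits_a),
        removed=sorted(bits_a - bits_b),
        class_changes=changes,
        same_root=bool(spine_a and spine_b and spine_a[0] == spine_b[0]),
    )


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def export_flowchart(chart: Flowchart, format: str = "dot") -> str:
    """Render a flowchart to DOT, indented text, or JSON."""
    if format == "json":
        return json.dumps(chart.to_dict(), indent=1, sort_keys=True)
    if format == "text":
        lines: list[str] = []

        def walk(node: ChartNode, indent: int) -> None:
            pad = "  " * indent
            if node.kind == "class":
                lines.append(f"{pad}-> {CLASS_NAMES[node.label]} (p={node.probability:.3f})")
                return
            lines.append(f"{pad}if contains {node.description}:")
            walk(node.yes, indent + 1)
            lines.append(f"{pad}else:")
            walk(node.no, indent + 1)

        walk(chart.root, 0)
        return "\n".join(lines) + "\n"
    if format == "dot":
        lines = ["digraph reactivity {", '  node [shape=box, fontname="Helvetica"];']
        counter = [0]

        def emit(node: ChartNode) -> str:
            nid = f"n{counter[0]}"
            counter[0] += 1
            if node.kind == "class":
                color = "palegreen" if node.label == REACTIVE else "lightcoral"
                lines.append(
                    f'  {nid} [label="{CLASS_NAMES[node.label]}", shape=oval,'
                    f' style=filled, fillcolor={color}];'
                )
                return nid
            lines.append(
                f'  {nid} [label="{_dot_escape(node.description)}\\n'
                f'support={node.support:.2f}"];'
            )
            yid, noid = emit(node.yes), emit(node.no)
            lines.append(f'  {nid} -> {yid} [label="yes"];')
            lines.append(f'  {nid} -> {noid} [label="no"];')
            return nid

        emit(chart.root)
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown flowchart format {format!r}")


def reference_chart() -> Flowchart:
    """Static published reference flowchart (synthetic bit numbering).

    Encodes the published seven-check sequence for the 70%-cutoff, radius-1
    model as a regression/demo fixture: aliphatic sulfoxide, heteroaromatic
    ring nitrogen with three substituents, sp2-sp2 junction, aryl sulfoxide,
    terminal carbon, terminal oxygen/carbonyl, hydroxylamino.  Bit indices
    are synthetic placeholders (0..6), not hashed fingerprint columns.
    """
    checks = [
        ("[CX4]-[SX3]=O", "sulfoxide with >=1 aliphatic carbon", REACTIVE, None),
        ("[nX3](:*)(:*)-*", "heteroaromatic ring N with three substituents", REACTIVE, None),
        ("[CX3]=[CX3]", "junction between sp2 atoms", REACTIVE, None),
        ("c-[SX3](=O)-c", "sulfoxide between aromatic rings", REACTIVE, None),
        ("[CX4H3]", "terminal carbon", None, UNREACTIVE),
        ("[OX1]", "terminal oxygen or carbonyl", UNREACTIVE, None),
        ("[NX3]-[OX2H1]", "hydroxylamino", REACTIVE, UNREACTIVE),
    ]
    node: ChartNode = ChartNode(kind="class", label=UNREACTIVE, probability=0.0)
    for i in range(len(checks) - 1, -1, -1):
        smarts, name, yes_cls, no_cls = checks[i]
        yes = (
            ChartNode(kind="class", label=yes_cls, probability=float(yes_cls == REACTIVE))
            if yes_cls is not None
            else node
        )
        no = (
            ChartNode(kind="class", label=no_cls, probability=float(no_cls == REACTIVE))
            if no_cls is not None
            else node
        )
        node = ChartNode(
            kind="check", bit=i, description=f"{name} ({smarts})", yes=yes, no=no
        )
    return Flowchart(root=node, n_bits=7, provenance={"source": "published reference"})
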