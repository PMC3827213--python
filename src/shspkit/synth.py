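"""Synthetic sHSP family generator.

Emulates the four sequence classes the analysis distinguishes — cyanophage,
bacterial class A, class B / plant type, and cyanobacterial — as templates
sharing a common 160-residue layout:

* N-terminal arm, columns 1-55, ending in the conserved double proline;
* α-crystallin domain (ACD), columns 56-147 (92 columns), carrying the
  β2-β9 strands, the L57 loop at columns 109-121 with an acidic residue at
  the canonical column 117, and the conserved β7 arginine at column 124;
* short C-terminal extension, columns 148-160, starting with the conserved
  proline and carrying the class's anchoring module (CAM).

Class markers planted on top of the shared layout: the cyanophage signature
P-P-[YF]-N-[ILV]-[IV]-x(9)-[EQ] across β2-β3 (columns 57-72), an A-G doublet
in L/F sandwich (columns 97-100) for the cyanophage and class A templates, a
P-G doublet for the plant and cyanobacterial templates, a classical CAM
(L-X-[ILV]) for cyanophage/class A/plant and the triple hydrophobic CAM
(I/V-X-I/L/V-X-I/L/V) for the cyanobacterial template.  Templates are
repaired after construction so each class's planted markers are its only
marker instances.

Families evolve along a planted-clade tree: one Yule subtree per class glued
to a fixed backbone.  Each site substitutes with probability μ per branch
(marker columns with probability ρ·μ), to a uniformly random different
residue.  Branch lengths shape the tree metric only, never the substitution
count — the simplest model whose per-branch divergence is exactly binomial
and therefore directly testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import CYANOPHAGE_SIGNATURE, scan_pattern
from .phylo import PhyloTree
from .seqio import AMINO_ACIDS, SequenceRecord

TEMPLATE_LENGTH = 160
N_ARM = (1, 55)
ACD = (56, 147)
C_EXT = (148, 160)

#: reference feature layout, 1-based inclusive columns
FEATURE_LAYOUT: dict[str, tuple[int, int]] = {
    "beta2": (57, 64),
    "beta3": (67, 74),
    "beta4": (79, 86),
    "beta5": (90, 96),
    "beta6": (99, 105),
    "L57": (109, 121),
    "beta7": (122, 128),
    "beta8": (131, 138),
    "beta9": (141, 146),
}
BETA7_ARG_COLUMN = 124
ACIDIC_PARTNER_COLUMN = 117
SIGNATURE_COLUMNS = (57, 72)
DOUBLET_COLUMNS = (98, 99)

CLASS_KEYS = {
    "cyanophage_like": "cyanophage",
    "bacterial_class_A_like": "classA",
    "class_B_plant_like": "plant",
    "cyanobacterial_like": "cyanobact",
}
KEY_TO_LABEL = {v: k for k, v in CLASS_KEYS.items()}

# class C-terminal extensions (columns 148-160), hand-designed so that the
# intended CAM is the only CAM-shaped window and no stray A-G/P-G occurs
_C_EXT_SEQS = {
    "cyanophage_like": "PKLAVAEKDNKTE",     # classical CAM L150-x-V152
    "bacterial_class_A_like": "PQLAIEKTDNRSE"[:13],  # classical CAM L150-x-I152
    "class_B_plant_like": "PDLAIEKTNQSSE"[:13],      # classical CAM L150-x-I152
    "cyanobacterial_like": "PEIAVALKEDNSR",  # triple CAM I150-V152-L154
}
_CAM_TRUTH = {
    "cyanophage_like": ("cam_classical", (150, 152)),
    "bacterial_class_A_like": ("cam_classical", (150, 152)),
    "class_B_plant_like": ("cam_classical", (150, 152)),
    "cyanobacterial_like": ("cam_triple", (150, 152, 154)),
}

_TEMPLATE_SEED = 777003       # internal constant: fixes the template scaffold
_CLASS_DIVERGENCE = 0.30      # scaffold fraction differing between classes


class SynthError(ValueError):
    """Simulator misconfiguration."""


@dataclass(frozen=True)
class ClassTemplate:
    label: str
    sequence: str
    protected_columns: frozenset[int]
    signature_start: int | None
    doublet_kind: str
    cam_kind: str
    cam_positions: tuple[int, ...]


def _mutate_sites(seq: list[str], sites: np.ndarray, rng: np.random.Generator) -> None:
    for i in np.flatnonzero(sites):
        current = seq[i]
        choices = [a for a in AMINO_ACIDS if a != current]
        seq[i] = choices[rng.integers(len(choices))]


def _strip_doublets(seq: list[str], keep: tuple[int, int] | None) -> None:
    """Replace the G of any unintended A-G/P-G dipeptide (T never re-forms one)."""
    for i in range(len(seq) - 1):
        if seq[i] in "AP" and seq[i + 1] == "G":
            if keep and (i + 1, i + 2) == keep:
                continue
            seq[i + 1] = "T"


def _break_signature(seq: list[str]) -> None:
    """Destroy accidental signature matches (non-cyanophage templates)."""
    while True:
        rec = SequenceRecord(id="tmp", residues="".join(seq))
        hits = scan_pattern(CYANOPHAGE_SIGNATURE, rec)
        if not hits:
            return
        seq[hits[0].start + 2] = "S"  # the N element position


def build_templates() -> dict[str, ClassTemplate]:
    """Construct the four class templates deterministically."""
    rng = np.random.default_rng(_TEMPLATE_SEED)
    base = [AMINO_ACIDS[i] for i in rng.integers(20, size=TEMPLATE_LENGTH)]
    templates: dict[str, ClassTemplate] = {}
    for label in CLASS_KEYS:
        seq = list(base)
        diverge = rng.random(TEMPLATE_LENGTH) < _CLASS_DIVERGENCE
        _mutate_sites(seq, diverge, rng)

        # shared layout (0-based indexing into seq)
        seq[53], seq[54] = "P", "P"          # arm-terminal double proline
        seq[55] = "S"                        # ACD start; breaks a spurious signature at 54
        seq[ACIDIC_PARTNER_COLUMN - 1] = "E"
        seq[BETA7_ARG_COLUMN - 1] = "R"
        seq[C_EXT[0] - 1 : C_EXT[1]] = list(_C_EXT_SEQS[label])

        protected = {54, 55, ACIDIC_PARTNER_COLUMN, BETA7_ARG_COLUMN, C_EXT[0]}
        protected.update(range(min(_CAM_TRUTH[label][1]), max(_CAM_TRUTH[label][1]) + 1))

        signature_start: int | None = None
        if label == "cyanophage_like":
            seq[56:62] = list("PPYNIV")
            seq[71] = "E"
            signature_start = SIGNATURE_COLUMNS[0]
            protected.update(range(SIGNATURE_COLUMNS[0], SIGNATURE_COLUMNS[1] + 1))

        if label in ("cyanophage_like", "bacterial_class_A_like"):
            seq[96:100] = list("LAGF")       # A-G doublet in the class-A sandwich
            doublet_kind = "doublet_AG"
            protected.update(range(97, 101))
        else:
            seq[96:100] = list("SPGK")       # P-G doublet, neutral context
            doublet_kind = "doublet_PG"
            protected.update(DOUBLET_COLUMNS)

        _strip_doublets(seq, keep=DOUBLET_COLUMNS)
        if label != "cyanophage_like":
            _break_signature(seq)

        cam_kind, cam_positions = _CAM_TRUTH[label]
        templates[label] = ClassTemplate(
            label=label,
            sequence="".join(seq),
            protected_columns=frozenset(protected),
            signature_start=signature_start,
            doublet_kind=doublet_kind,
            cam_kind=cam_kind,
            cam_positions=cam_positions,
        )
    return templates


TEMPLATES = build_templates()


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated family.

    ``mu`` is the per-branch per-site substitution probability; marker
    columns substitute with probability ``rho * mu``.  ``indel_rate`` is the
    expected number of single-residue indel events per branch (default 0, so
    that truth-table coordinates stay valid).
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {label: 5 for label in CLASS_KEYS}
    )
    birth_rate: float = 1.0
    mu: float = 0.05
    rho: float = 0.1
    indel_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.mu < 1:
            raise SynthError("mu must be in [0, 1)")
        if not 0 <= self.rho <= 1:
            raise SynthError("rho must be in [0, 1]")
        if self.indel_rate < 0:
            raise SynthError("indel_rate must be >= 0")
        unknown = set(self.n_per_class) - set(CLASS_KEYS)
        if unknown:
            raise SynthError(f"unknown classes {sorted(unknown)}")
        if any(n < 1 for n in self.n_per_class.values()):
            raise SynthError("each class needs at least one taxon")
        if sum(self.n_per_class.values()) < 3:
            raise SynthError("need at least 3 taxa in total")


def _yule_subtree(labels: list[str], rate: float, rng: np.random.Generator) -> str:
    """Newick fragment (no trailing ;) of an ultrametric Yule tree."""
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:{rng.exponential(1.0 / rate):.10g}"

    class _Lineage:
        __slots__ = ("children", "length")

        def __init__(self) -> None:
            self.children: list["_Lineage"] | None = None
            self.length = 0.0

    root_children = [_Lineage(), _Lineage()]
    active = list(root_children)
    while len(active) < n:
        dt = rng.exponential(1.0 / (len(active) * rate))
        for nd in active:
            nd.length += dt
        chosen = active.pop(int(rng.integers(len(active))))
        chosen.children = [_Lineage(), _Lineage()]
        active.extend(chosen.children)
    dt = rng.exponential(1.0 / (len(active) * rate))
    for nd in active:
        nd.length += dt

    leaf_iter = iter(labels)

    def render(nd: "_Lineage") -> str:
        if nd.children is None:
            return f"{next(leaf_iter)}:{nd.length:.10g}"
        return f"({render(nd.children[0])},{render(nd.children[1])}):{nd.length:.10g}"

    return f"({render(root_children[0])},{render(root_children[1])}):0"


def taxon_labels(config: SimulationConfig) -> dict[str, list[str]]:
    """Leaf labels per class, e.g. cyanophage_001."""
    return {
        label: [f"{CLASS_KEYS[label]}_{i:03d}" for i in range(n)]
        for label, n in config.n_per_class.items()
    }


def simulate_tree(config: SimulationConfig) -> PhyloTree:
    """Planted-clade tree: one Yule subtree per class on a fixed backbone.

    Each class's members form a single subtree, so every class is
    monophyletic in the generating topology by construction.
    """
    rng = np.random.default_rng(config.seed)
    labels = taxon_labels(config)
    subtrees = {
        label: _yule_subtree(labels[label], config.birth_rate, rng)
        for label in sorted(labels)
    }
    parts = [subtrees[label] for label in sorted(subtrees)]
    # fixed backbone over up to four class clades, 0.5-unit internal edges
    while len(parts) > 2:
        a = parts.pop(0)
        b = parts.pop(0)
        parts.append(f"({_rebranch(a, 0.5)},{_rebranch(b, 0.5)}):0.5")
    if len(parts) == 2:
        newick = f"({_rebranch(parts[0], 0.5)},{_rebranch(parts[1], 0.5)});"
    else:
        newick = f"({parts[0]});"
    return PhyloTree.from_newick(newick)


def _rebranch(fragment: str, length: float) -> str:
    """Replace the root branch length of a newick fragment."""
    head, _, _ = fragment.rpartition(":")
    return f"{head}:{length:.10g}"


def _mutate_branch(
    seq: str, protected: frozenset[int], config: SimulationConfig, rng: np.random.Generator
) -> str:
    """One branch of evolution: per-site Bernoulli substitution."""
    chars = list(seq)
    L = len(chars)
    rates = np.full(L, config.mu)
    for col in protected:
        if col <= L:
            rates[col - 1] = config.rho * config.mu
    hits = rng.random(L) < rates
    _mutate_sites(chars, hits, rng)
    if config.indel_rate > 0:
        for _ in range(rng.poisson(config.indel_rate)):
            pos = int(rng.integers(len(chars)))
            if rng.random() < 0.5 and len(chars) > 1:
                del chars[pos]
            else:
                chars.insert(pos, AMINO_ACIDS[rng.integers(20)])
    return "".join(chars)


def evolve_family(
    tree: PhyloTree, config: SimulationConfig
) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Evolve class templates down their clades; return sequences + truth.

    The truth table records, per leaf, the planted class and feature
    coordinates (valid as given only when ``indel_rate`` is 0).
    """
    rng = np.random.default_rng(config.seed + 1)
    labels = taxon_labels(config)
    leaf_to_class = {leaf: label for label, lv in labels.items() for leaf in lv}
    expected = set(leaf_to_class)
    if tree.taxa != expected:
        raise SynthError("tree leaves do not match the configured taxa")

    # class clade root = node whose leaf set equals the class's leaves
    dtree = tree.tree
    sequences: dict[str, str] = {}
    for label in sorted(labels):
        template = TEMPLATES[label]
        members = set(labels[label])
        root = None
        if members == expected:
            root = dtree.seed_node
        else:
            for node in dtree.preorder_node_iter():
                if {l.taxon.label for l in node.leaf_iter()} == members:
                    root = node
                    break
        if root is None:
            raise SynthError(f"no clade found for class {label}")
        seqs_at: dict[int, str] = {id(root): template.sequence}
        for node in root.preorder_iter():
            if node is root:
                continue
            parent_seq = seqs_at[id(node.parent_node)]
            seqs_at[id(node)] = _mutate_branch(
                parent_seq, template.protected_columns, config, rng
            )
        for leaf in root.leaf_iter():
            sequences[leaf.taxon.label] = seqs_at[id(leaf)]

    records = [
        SequenceRecord(id=leaf, residues=sequences[leaf])
        for lbl in sorted(labels)
        for leaf in labels[lbl]
    ]
    rows = []
    for rec in records:
        t = TEMPLATES[leaf_to_class[rec.id]]
        rows.append(
            {
                "taxon": rec.id,
                "class": t.label,
                "signature_start": t.signature_start if t.signature_start else -1,
                "doublet_kind": t.doublet_kind,
                "doublet_start": DOUBLET_COLUMNS[0],
                "cam_kind": t.cam_kind,
                "cam_positions": ",".join(map(str, t.cam_positions)),
                "beta7_column": BETA7_ARG_COLUMN,
                "acd_start": ACD[0],
                "acd_end": ACD[1],
            }
        )
    return records, pd.DataFrame(rows)


def simulate_family(
    config: SimulationConfig,
) -> tuple[PhyloTree, list[SequenceRecord], pd.DataFrame]:
    """Convenience wrapper: tree + evolved sequences + truth table."""
    tree = simulate_tree(config)
    records, truth = evolve_family(tree, config)
    return tree, records, truth
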