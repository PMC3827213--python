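"""Rule-based class assignment from annotated motif evidence.

The cascade is ordered by marker specificity, most diagnostic first:

1. the cyanophage signature pattern (anywhere in the sequence) — cyanophage;
2. a triple CAM in the C-terminal extension together with a P-G doublet —
   cyanobacterial;
3. an A-G doublet — bacterial class A (a marker this type shares with animal
   sHSPs, so the label reads "class-A-like", not a taxonomic call);
4. a P-G doublet — class B / plant type;
5. otherwise unclassified.

Exactly one rule fires; every hit supporting the fired rule is kept as
evidence.  Sequences carrying both doublets fall to rule 3 — the tie has no
published resolution, and the ordering here is a documented package choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .architecture import RegionAnnotation
from .motifs import MotifHit
from .pattern import PatternHit
from .seqio import CatalogEntry

LABELS = (
    "cyanophage_like",
    "bacterial_class_A_like",
    "class_B_plant_like",
    "cyanobacterial_like",
    "unclassified",
)


@dataclass(frozen=True)
class ClassificationResult:
    sequence_id: str
    label: str
    rule_fired: str
    evidence: tuple[PatternHit | MotifHit, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r}")
        if self.label != "unclassified" and not self.evidence:
            raise ValueError("a classified result needs supporting evidence")


def classify_sequence(
    annotation: RegionAnnotation,
    pattern_hits: list[PatternHit],
    motif_hits: list[MotifHit],
) -> ClassificationResult:
    """Run the specificity cascade on one sequence's evidence."""
    sid = annotation.sequence_id
    if pattern_hits:
        return ClassificationResult(sid, "cyanophage_like", "signature", tuple(pattern_hits))

    triples = [h for h in motif_hits if h.kind == "cam_triple" and h.region == "c_ext"]
    ag = [h for h in motif_hits if h.kind == "doublet_AG"]
    pg = [h for h in motif_hits if h.kind == "doublet_PG"]
    if triples and pg:
        return ClassificationResult(
            sid, "cyanobacterial_like", "triple_cam_and_pg", tuple(triples + pg)
        )
    if ag:
        return ClassificationResult(sid, "bacterial_class_A_like", "ag_doublet", tuple(ag))
    if pg:
        return ClassificationResult(sid, "class_B_plant_like", "pg_doublet", tuple(pg))
    return ClassificationResult(sid, "unclassified", "none")


def summarize(
    results: list[ClassificationResult],
    catalog: list[CatalogEntry] | None = None,
    truth: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Tabulate label counts; with a catalog or truth map, cross-tabulate.

    Returns a tidy DataFrame: with no grouping information, one row per label
    with its count; otherwise a label x group confusion table in long form.
    """
    if not results:
        raise ValueError("nothing to summarize")
    df = pd.DataFrame(
        {"sequence_id": [r.sequence_id for r in results],
         "label": [r.label for r in results]}
    )
    group_of: dict[str, str] = {}
    if catalog is not None:
        group_of.update({e.accession: e.group for e in catalog})
        group_of.update({e.label: e.group for e in catalog})
    if truth is not None:
        group_of.update(truth)
    if group_of:
        df["group"] = df.sequence_id.map(group_of).fillna("unknown")
        out = df.groupby(["label", "group"], as_index=False).size().rename(columns={"size": "count"})
    else:
        out = df.groupby("label", as_index=False).size().rename(columns={"size": "count"})
    assert out["count"].sum() == len(results)
    return out


def accuracy(results: list[ClassificationResult], truth: dict[str, str]) -> float:
    """Fraction of sequences whose assigned label equals the true class label."""
    if not results:
        raise ValueError("no results")
    hits = sum(1 for r in results if truth.get(r.sequence_id) == r.label)
    return hits / len(results)
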