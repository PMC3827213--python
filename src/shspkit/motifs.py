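"""Detection of the short sHSP motifs that carry class information.

* C-terminal anchoring module (CAM) variants in the C-terminal extension:
  the classical two-hydrophobic form L-X-[ILV], the non-classical pairs
  A-X-P / L-X-G / L-X-A seen in *Prochlorococcus* phages, and the triple
  hydrophobic form I/V-X-I/L/V-X-I/L/V characteristic of cyanobacterial
  sHSPs.
* A-G and P-G doublets (bacterial class A vs class B / plant markers) in and
  around the ACD, with their hydrophobic/aromatic sandwich context.
* The conserved β7 arginine (whose loss or substitution — K in phage S-CRM01,
  N in S-PM2/S-CAM1/Syn1 — the annotation records rather than judges).
* Acidic salt-bridge partners (D/E) for that arginine inside the L57 loop,
  flagging the canonical reference position 117.

Every finder enumerates all matching windows; overlapping hits are all
reported and a triple CAM never suppresses the pair CAMs it contains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import RegionAnnotation
from .seqio import SequenceRecord

AROMATIC = frozenset("FYW")

#: CAM pair variants: kind -> (first-residue set, third-residue set)
CAM_PAIR_RULES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "cam_classical": (frozenset("L"), frozenset("ILV")),
    "cam_AXP": (frozenset("A"), frozenset("P")),
    "cam_LXG": (frozenset("L"), frozenset("G")),
    "cam_LXA": (frozenset("L"), frozenset("A")),
}

#: triple CAM: [IV]-X-[ILV]-X-[ILV]
CAM_TRIPLE_RULE = (frozenset("IV"), frozenset("ILV"), frozenset("ILV"))

#: how far beyond the ACD (both sides) the doublet search window extends
DOUBLET_FLANK = 10


@dataclass(frozen=True)
class MotifHit:
    """One detected motif instance.

    ``positions`` are 1-based indices of the *informative* residues (the X
    spacers of a CAM are not listed); ``residues`` are the letters at those
    positions and ``region`` locates the first informative residue.
    """

    sequence_id: str
    kind: str
    positions: tuple[int, ...]
    residues: str
    region: str
    context_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("motif positions must be strictly ascending")


def _mkhit(record: SequenceRecord, annotation: RegionAnnotation, kind: str,
           positions: tuple[int, ...], flags: dict[str, bool] | None = None) -> MotifHit:
    return MotifHit(
        sequence_id=record.id,
        kind=kind,
        positions=positions,
        residues="".join(record.residues[p - 1] for p in positions),
        region=annotation.region_of(positions[0]),
        context_flags=flags or {},
    )


def find_cam(record: SequenceRecord, annotation: RegionAnnotation) -> list[MotifHit]:
    """Find CAM variants, restricted to the C-terminal extension.

    A window counts only when it lies entirely inside the extension: CAMs are
    anchoring modules of the extension by definition, and hits must not cross
    the ACD boundary.  Returns hits sorted by start position, pair kinds
    before the triple at equal start.
    """
    if annotation.c_ext is None:
        return []
    lo, hi = annotation.c_ext
    seq = record.residues
    hits: list[MotifHit] = []
    for start in range(lo, hi + 1):
        # pair CAMs occupy [start, start+2]
        if start + 2 <= hi:
            a, b = seq[start - 1], seq[start + 1]
            for kind, (first, third) in CAM_PAIR_RULES.items():
                if a in first and b in third:
                    hits.append(_mkhit(record, annotation, kind, (start, start + 2)))
        # triple CAM occupies [start, start+4]
        if start + 4 <= hi:
            r1, r2, r3 = seq[start - 1], seq[start + 1], seq[start + 3]
            s1, s2, s3 = CAM_TRIPLE_RULE
            if r1 in s1 and r2 in s2 and r3 in s3:
                hits.append(
                    _mkhit(record, annotation, "cam_triple", (start, start + 2, start + 4))
                )
    hits.sort(key=lambda h: (h.positions[0], h.kind))
    return hits


def find_doublets(record: SequenceRecord, annotation: RegionAnnotation) -> list[MotifHit]:
    """Find A-G and P-G dipeptides in the ACD plus a 10-residue flank.

    Context flags record the class-A sandwich described for the A-G doublet:
    ``preceded_by_L`` (aliphatic L immediately before) and
    ``followed_by_aromatic`` (F/Y/W immediately after).
    """
    lo = max(1, annotation.acd_start - DOUBLET_FLANK)
    hi = min(record.length, annotation.acd_end + DOUBLET_FLANK)
    seq = record.residues
    hits: list[MotifHit] = []
    for start in range(lo, hi):  # dipeptide [start, start+1] within window
        pair = seq[start - 1 : start + 1]
        if pair not in ("AG", "PG"):
            continue
        flags = {
            "preceded_by_L": start >= 2 and seq[start - 2] == "L",
            "followed_by_aromatic": start + 1 < record.length and seq[start + 1] in AROMATIC,
        }
        kind = "doublet_AG" if pair == "AG" else "doublet_PG"
        hits.append(_mkhit(record, annotation, kind, (start, start + 1), flags))
    return hits


def beta7_residue(record: SequenceRecord, annotation: RegionAnnotation) -> MotifHit:
    """Report the residue at the mapped β7-arginine column."""
    pos = annotation.beta7_column
    b7 = annotation.strand_map.get("beta7")
    if b7 is None or not (b7[0] <= pos <= b7[1]) or not (1 <= pos <= record.length):
        raise ValueError(f"{record.id}: beta7 arginine column could not be mapped")
    res = record.residues[pos - 1]
    return _mkhit(
        record,
        annotation,
        "beta7_residue",
        (pos,),
        {"is_R": res == "R", "is_basic": res in "RK", "is_N": res == "N"},
    )


def acidic_partners(record: SequenceRecord, annotation: RegionAnnotation) -> list[MotifHit]:
    """D/E residues inside the L57 loop: candidate salt-bridge partners.

    Each hit carries its reference column (``ref_column`` in the flags via
    position arithmetic) and a flag marking the canonical partner column 117.
    """
    lo, hi = annotation.l57_interval
    l57_ref_lo = annotation.l57_ref_start
    hits: list[MotifHit] = []
    for pos in range(lo, hi + 1):
        if record.residues[pos - 1] in "DE":
            ref_col = l57_ref_lo + (pos - lo)
            hits.append(
                _mkhit(record, annotation, "acidic_partner", (pos,),
                       {"at_117": ref_col == 117}),
            )
    return hits


def find_all_motifs(record: SequenceRecord, annotation: RegionAnnotation) -> list[MotifHit]:
    """All motif evidence for one annotated sequence (CAMs, doublets, β7)."""
    hits = find_cam(record, annotation) + find_doublets(record, annotation)
    try:
        hits.append(beta7_residue(record, annotation))
    except ValueError:
        pass  # unmappable β7 column: no evidence recorded
    hits.extend(acidic_partners(record, annotation))
    return hits
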