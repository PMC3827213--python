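"""CAM, doublet, β7 and L57-partner detection vs brute-force enumeration."""

import numpy as np
import pytest

from shspkit.architecture import RegionAnnotation
from shspkit.motifs import (
    CAM_PAIR_RULES,
    CAM_TRIPLE_RULE,
    DOUBLET_FLANK,
    acidic_partners,
    beta7_residue,
    find_all_motifs,
    find_cam,
    find_doublets,
)
from shspkit.seqio import SequenceRecord

from conftest import random_protein


def make_annotation(length, acd_start, acd_end, beta7_offset=60, l57=(50, 62)):
    """Hand-built annotation for motif tests (positions in sequence coords)."""
    b7col = acd_start + beta7_offset
    return RegionAnnotation(
        sequence_id="s",
        length=length,
        acd_start=acd_start,
        acd_end=acd_end,
        strand_map={"beta7": (b7col - 3, b7col + 3)},
        l57_interval=(acd_start + l57[0], acd_start + l57[1]),
        beta7_column=b7col,
        acd_score=0.0,
        l57_ref_start=109,
    )


def seq_with_ext(ext: str, acd_len: int = 80) -> tuple[SequenceRecord, RegionAnnotation]:
    body = "M" * acd_len
    rec = SequenceRecord(id="s", residues=body + ext)
    ann = make_annotation(rec.length, 1, acd_len)
    return rec, ann


def rel(hits, offset):
    return [(h.kind, tuple(p - offset for p in h.positions)) for h in hits]


def test_classical_cam_in_extension():
    rec, ann = seq_with_ext("AALAVAA")
    hits = find_cam(rec, ann)
    assert rel(hits, ann.acd_end) == [("cam_classical", (3, 5))]
    assert hits[0].residues == "LV"
    assert hits[0].region == "c_ext"


def test_triple_cam_in_extension():
    rec, ann = seq_with_ext("IAVAL")
    hits = find_cam(rec, ann)
    kinds = rel(hits, ann.acd_end)
    assert ("cam_triple", (1, 3, 5)) in kinds
    triple = next(h for h in hits if h.kind == "cam_triple")
    assert triple.residues == "IVL"


def test_triple_does_not_suppress_contained_pairs():
    # L-A-L-A-V: overlapping classical pairs at (1,3) and (3,5)
    rec, ann = seq_with_ext("LALAV")
    kinds = rel(find_cam(rec, ann), ann.acd_end)
    assert ("cam_classical", (1, 3)) in kinds
    assert ("cam_classical", (3, 5)) in kinds


def test_nonclassical_pair_cams():
    for ext, kind in [("AAP", "cam_AXP"), ("LAG", "cam_LXG"), ("LCA", "cam_LXA")]:
        rec, ann = seq_with_ext("KK" + ext)
        kinds = [h.kind for h in find_cam(rec, ann)]
        assert kind in kinds, ext


def test_empty_extension_gives_no_cams():
    rec = SequenceRecord(id="s", residues="M" * 50 + "LAV")
    ann = make_annotation(53, 1, 53)  # ACD covers everything
    assert ann.c_ext is None
    assert find_cam(rec, ann) == []


def test_cam_never_crosses_into_acd():
    # L sits in the ACD, V in the extension: the window must not count
    rec = SequenceRecord(id="s", residues="M" * 49 + "LAV" + "AAAA")
    ann = make_annotation(rec.length, 1, 51)  # L at 50, A at 51 inside ACD
    for h in find_cam(rec, ann):
        assert all(p > ann.acd_end for p in h.positions)


def test_doublet_context_flags():
    # ...L A G F... inside the ACD
    rec = SequenceRecord(id="s", residues="M" * 20 + "LAGF" + "M" * 40)
    ann = make_annotation(rec.length, 5, 60)
    hits = find_doublets(rec, ann)
    assert len(hits) == 1
    h = hits[0]
    assert h.kind == "doublet_AG"
    assert h.positions == (22, 23)
    assert h.context_flags == {"preceded_by_L": True, "followed_by_aromatic": True}


def test_pg_doublet_neutral_context():
    rec = SequenceRecord(id="s", residues="M" * 20 + "PGK" + "M" * 40)
    ann = make_annotation(rec.length, 5, 60)
    hits = find_doublets(rec, ann)
    assert [h.kind for h in hits] == ["doublet_PG"]
    assert hits[0].context_flags == {"preceded_by_L": False, "followed_by_aromatic": False}


def test_no_doublets_empty():
    rec = SequenceRecord(id="s", residues="M" * 60)
    ann = make_annotation(60, 5, 55)
    assert find_doublets(rec, ann) == []


def test_doublet_window_respected():
    # A-G more than 10 residues before the ACD start is outside the window
    rec = SequenceRecord(id="s", residues="AG" + "M" * 28 + "K" * 60)
    ann = make_annotation(rec.length, 30, 85)
    assert find_doublets(rec, ann) == []
    ann2 = make_annotation(rec.length, 8, 85)  # now within ACD-10
    assert [h.kind for h in find_doublets(rec, ann2)] == ["doublet_AG"]


@pytest.mark.parametrize(
    "residue,flags",
    [
        ("R", {"is_R": True, "is_basic": True, "is_N": False}),
        ("K", {"is_R": False, "is_basic": True, "is_N": False}),
        ("N", {"is_R": False, "is_basic": False, "is_N": True}),
    ],
)
def test_beta7_residue_flags(residue, flags):
    body = list("M" * 100)
    ann = make_annotation(100, 5, 95, beta7_offset=60)
    body[ann.beta7_column - 1] = residue
    rec = SequenceRecord(id="s", residues="".join(body))
    hit = beta7_residue(rec, ann)
    assert hit.residues == residue
    assert hit.context_flags == flags


def test_acidic_partners_at_117():
    body = list("M" * 100)
    ann = make_annotation(100, 5, 95, l57=(50, 62))
    lo, hi = ann.l57_interval
    # plant one E at the position mapping to reference column 117
    target = lo + (117 - 109)
    body[target - 1] = "E"
    rec = SequenceRecord(id="s", residues="".join(body))
    hits = acidic_partners(rec, ann)
    assert len(hits) == 1
    assert hits[0].positions == (target,)
    assert hits[0].context_flags["at_117"] is True


def test_acidic_partners_counts():
    body = list("M" * 100)
    ann = make_annotation(100, 5, 95, l57=(50, 54))
    lo, hi = ann.l57_interval
    body[lo - 1 : hi] = list("DADED")
    rec = SequenceRecord(id="s", residues="".join(body))
    hits = acidic_partners(rec, ann)
    assert len(hits) == 4  # D, D, E, D
    rec2 = SequenceRecord(id="s", residues="M" * 100)
    assert acidic_partners(rec2, ann) == []


# ---------------------------------------------------------------------------
# brute-force oracle equality
# ---------------------------------------------------------------------------

def oracle_cams(seq: str, lo: int, hi: int):
    out = set()
    for i in range(lo, hi + 1):
        if i + 2 <= hi:
            for kind, (first, third) in CAM_PAIR_RULES.items():
                if seq[i - 1] in first and seq[i + 1] in third:
                    out.add((kind, (i, i + 2)))
        if i + 4 <= hi:
            s1, s2, s3 = CAM_TRIPLE_RULE
            if seq[i - 1] in s1 and seq[i + 1] in s2 and seq[i + 3] in s3:
                out.add(("cam_triple", (i, i + 2, i + 4)))
    return out


def oracle_doublets(seq: str, lo: int, hi: int):
    out = set()
    for i in range(max(1, lo), min(len(seq) - 1, hi - 1) + 1):
        pair = seq[i - 1 : i + 1]
        if pair in ("AG", "PG"):
            out.add((f"doublet_{pair}", (i, i + 1)))
    return out


def test_motif_finders_equal_brute_force(rng):
    """Exact hit-set equality on random sequences and random architectures
    (spot check; full 500-sequence comparison in the acceptance suite)."""
    for _ in range(100):
        L = int(rng.integers(30, 120))
        seq = random_protein(rng, L)
        acd_start = int(rng.integers(1, max(2, L // 3)))
        acd_end = int(rng.integers(acd_start + 10, L + 1))
        acd_end = min(acd_end, L)
        ann = RegionAnnotation(
            sequence_id="s", length=L, acd_start=acd_start, acd_end=acd_end,
            strand_map={}, l57_interval=(acd_start, min(acd_end, acd_start + 5)),
            beta7_column=acd_start, acd_score=0.0,
        )
        rec = SequenceRecord(id="s", residues=seq)
        got = {(h.kind, h.positions) for h in find_cam(rec, ann)}
        if ann.c_ext:
            assert got == oracle_cams(seq, ann.c_ext[0], ann.c_ext[1])
        else:
            assert got == set()
        lo = max(1, acd_start - DOUBLET_FLANK)
        hi = min(L, acd_end + DOUBLET_FLANK)
        got_d = {(h.kind, h.positions) for h in find_doublets(rec, ann)}
        assert got_d == oracle_doublets(seq, lo, hi)
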