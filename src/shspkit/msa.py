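"""Multiple alignment of sHSP sets and extraction of the phylogeny columns.

The aligner is a deterministic progressive scheme: global pairwise alignment
with affine gap costs (Gotoh), a guide tree from k-mer distances (average
linkage), and frequency-profile merging.  Determinism is load-bearing here —
identical inputs must give byte-identical alignments so that downstream
distances and trees are reproducible — which is why tie-breaking is pinned
(diagonal > up > left) instead of delegated to an external aligner.

``extract_region_columns`` implements the restriction used for tree building:
only the α-crystallin domain and the C-terminal extension carry phylogenetic
signal here; N-arm columns are dropped/masked by a 50%-occupancy rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .architecture import RegionAnnotation
from .seqio import AMINO_ACIDS, SequenceRecord

GAP = "-"
_ALPHABET = AMINO_ACIDS + "X"
_ALPHA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}


class MsaError(ValueError):
    """Alignment failure (bad inputs, empty region intersection, ...)."""


@dataclass(frozen=True)
class AlignParams:
    """Substitution table and affine gap costs.

    A gap of length k costs ``gap_open + (k - 1) * gap_extend``.  Defaults are
    the common protein settings (BLOSUM62, open 10, extend 0.5).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def substitution_matrix(self) -> np.ndarray:
        """Score table over the 20 amino acids + X, as a 21x21 array."""
        table = substitution_matrices.load(self.matrix_name)
        out = np.zeros((21, 21))
        for i, a in enumerate(_ALPHABET):
            for j, b in enumerate(_ALPHABET):
                out[i, j] = table[a][b]
        return out


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped rows keyed by sequence id (insertion-ordered)."""

    rows: dict[str, str]
    column_provenance: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) > 1:
            raise MsaError("alignment rows have unequal length")

    @property
    def ncols(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def degap(self, seq_id: str) -> str:
        return self.rows[seq_id].replace(GAP, "").replace(".", "")


def _traceback_gotoh(
    score: np.ndarray, open_: float, extend: float
) -> tuple[float, list[tuple[int, int]]]:
    """Global affine-gap DP over a precomputed (n x m) column-score table.

    Returns the optimal score and the alignment path as (i, j) steps where
    i/j are 0 for a gap.  Tie order during traceback: diagonal > up > left.
    """
    n, m = score.shape
    NEG = -np.inf
    M = np.full((n + 1, m + 1), NEG)   # last step: match
    Ix = np.full((n + 1, m + 1), NEG)  # last step: up (gap in second input)
    Iy = np.full((n + 1, m + 1), NEG)  # last step: left (gap in first input)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -open_ - (i - 1) * extend
    for j in range(1, m + 1):
        Iy[0, j] = -open_ - (j - 1) * extend
    for i in range(1, n + 1):
        Mi1, Ixi1, Iyi1 = M[i - 1], Ix[i - 1], Iy[i - 1]
        srow = score[i - 1]
        Mi, Ixi, Iyi = M[i], Ix[i], Iy[i]
        for j in range(1, m + 1):
            best_prev = max(Mi1[j - 1], Ixi1[j - 1], Iyi1[j - 1])
            Mi[j] = best_prev + srow[j - 1]
            Ixi[j] = max(Mi1[j] - open_, Ixi1[j] - extend, Iyi1[j] - open_)
            Iyi[j] = max(Mi[j - 1] - open_, Iyi[j - 1] - extend, Ixi[j - 1] - open_)
    final = max(M[n, m], Ix[n, m], Iy[n, m])

    # traceback with pinned preference: diagonal (M) > up (Ix) > left (Iy)
    path: list[tuple[int, int]] = []
    i, j = n, m
    eps = 1e-9
    if abs(M[n, m] - final) < eps:
        state = "M"
    elif abs(Ix[n, m] - final) < eps:
        state = "X"
    else:
        state = "Y"
    while i > 0 or j > 0:
        if state == "M":
            path.append((i, j))
            prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            i, j = i - 1, j - 1
            if abs(M[i, j] - prev) < eps:
                state = "M"
            elif abs(Ix[i, j] - prev) < eps:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            path.append((i, 0))
            val = Ix[i, j]
            if abs((M[i - 1, j] - open_) - val) < eps:
                state = "M"
            elif abs((Ix[i - 1, j] - extend) - val) < eps:
                state = "X"
            else:
                state = "Y"
            i -= 1
        else:
            path.append((0, j))
            val = Iy[i, j]
            if abs((M[i, j - 1] - open_) - val) < eps:
                state = "M"
            elif abs((Iy[i, j - 1] - extend) - val) < eps:
                state = "Y"
            else:
                state = "X"
            j -= 1
    path.reverse()
    return float(final), path


def _pair_score_table(a: str, b: str, sub: np.ndarray) -> np.ndarray:
    ia = np.array([_ALPHA_INDEX[c] for c in a])
    ib = np.array([_ALPHA_INDEX[c] for c in b])
    return sub[np.ix_(ia, ib)]


def pairwise_align(
    a: SequenceRecord, b: SequenceRecord, params: AlignParams | None = None
) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences with affine gap costs."""
    params = params or AlignParams()
    if a.length == 0 or b.length == 0:  # SequenceRecord forbids this, belt+braces
        raise MsaError("cannot align an empty sequence")
    sub = params.substitution_matrix()
    score, path = _traceback_gotoh(
        _pair_score_table(a.residues, b.residues, sub), params.gap_open, params.gap_extend
    )
    row_a, row_b = [], []
    for i, j in path:
        row_a.append(a.residues[i - 1] if i else GAP)
        row_b.append(b.residues[j - 1] if j else GAP)
    return Alignment({a.id: "".join(row_a), b.id: "".join(row_b)}), score


# ---------------------------------------------------------------------------
# progressive alignment
# ---------------------------------------------------------------------------

def _kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 - Jaccard similarity of k-mer sets; crude but fine for a guide tree."""
    sets = [frozenset(s[i : i + k] for i in range(max(1, len(s) - k + 1))) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            d[i, j] = d[j, i] = 1.0 - (inter / union if union else 0.0)
    return d


def _profile_freqs(rows: list[str]) -> np.ndarray:
    ncols = len(rows[0])
    freqs = np.zeros((ncols, 21))
    for row in rows:
        for c, ch in enumerate(row):
            idx = _ALPHA_INDEX.get(ch)
            if idx is not None:
                freqs[c, idx] += 1
    return freqs / len(rows)  # gap mass simply missing: gaps score 0


def _merge_profiles(
    rows_a: list[str], rows_b: list[str], sub: np.ndarray, params: AlignParams
) -> tuple[list[str], list[str]]:
    fa = _profile_freqs(rows_a)
    fb = _profile_freqs(rows_b)
    score = fa @ sub @ fb.T
    _, path = _traceback_gotoh(score, params.gap_open, params.gap_extend)
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    for i, j in path:
        for r, row in enumerate(rows_a):
            out_a[r] += row[i - 1] if i else GAP
        for r, row in enumerate(rows_b):
            out_b[r] += row[j - 1] if j else GAP
    return out_a, out_b


def progressive_align(
    records: list[SequenceRecord], params: AlignParams | None = None
) -> Alignment:
    """Progressive multiple alignment: k-mer guide tree + profile merging.

    Fully deterministic: same records (same order) give the same alignment.
    """
    params = params or AlignParams()
    if len(records) < 2:
        raise MsaError("progressive alignment needs at least 2 sequences")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise MsaError("duplicate sequence ids")
    sub = params.substitution_matrix()
    dm = _kmer_distance_matrix([r.residues for r in records])
    Z = linkage(squareform(dm, checks=False), method="average")

    # clusters[c] = (ordered member indices, aligned rows)
    clusters: dict[int, tuple[list[int], list[str]]] = {
        i: ([i], [records[i].residues]) for i in range(len(records))
    }
    nxt = len(records)
    for a_id, b_id, _, _ in Z:
        mem_a, rows_a = clusters.pop(int(a_id))
        mem_b, rows_b = clusters.pop(int(b_id))
        rows_a, rows_b = _merge_profiles(rows_a, rows_b, sub, params)
        clusters[nxt] = (mem_a + mem_b, rows_a + rows_b)
        nxt += 1
    members, rows = clusters.popitem()[1]
    aligned = {records[m].id: row for m, row in zip(members, rows)}
    # restore input order
    return Alignment({r.id: aligned[r.id] for r in records})


def extract_region_columns(
    alignment: Alignment, annotations: dict[str, RegionAnnotation]
) -> Alignment:
    """Keep the ACD + C-terminal-extension columns for phylogeny.

    A column is kept when at least 50% of rows place an ACD or C-extension
    residue in it; within kept columns, residues that belong to a row's N-arm
    are masked to gaps so arm residues never leak into the distance matrix.
    """
    missing = [i for i in alignment.ids if i not in annotations]
    if missing:
        raise MsaError(f"missing annotations for rows {missing}")
    ids = alignment.ids
    nrows = len(ids)
    # per row: residue position (1-based) at each alignment column, 0 for gap
    pos_maps: dict[str, list[int]] = {}
    for sid in ids:
        row = alignment.rows[sid]
        pos = 0
        pm = []
        for ch in row:
            if ch == GAP or ch == ".":
                pm.append(0)
            else:
                pos += 1
                pm.append(pos)
        pos_maps[sid] = pm

    kept: list[int] = []
    for c in range(alignment.ncols):
        in_region = 0
        for sid in ids:
            p = pos_maps[sid][c]
            if p and annotations[sid].region_of(p) != "n_arm":
                in_region += 1
        if in_region / nrows >= 0.5:
            kept.append(c)
    if not kept:
        raise MsaError("no columns are majority ACD/C-extension; nothing to extract")

    new_rows: dict[str, str] = {}
    for sid in ids:
        row = alignment.rows[sid]
        chars = []
        for c in kept:
            p = pos_maps[sid][c]
            if p and annotations[sid].region_of(p) != "n_arm":
                chars.append(row[c])
            else:
                chars.append(GAP)
        new_rows[sid] = "".join(chars)
    return Alignment(new_rows, column_provenance=tuple(c + 1 for c in kept))
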