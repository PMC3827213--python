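"""Domain-architecture annotation: locate the α-crystallin domain (ACD) and
delimit the flanking N-terminal arm and C-terminal extension.

The ACD is found by sliding an ungapped log-odds position-specific scoring
matrix (PSSM), built from a reference alignment, along the sequence and
taking the best-scoring window.  β-strand intervals (β2-β9), the L57 loop and
the conserved β7-arginine column are projected from reference-alignment
coordinates through the window offset.  All coordinates are 1-based inclusive,
matching how residue positions are printed in the sHSP literature (L142,
position 117, ...).

The reference alignment and its column→feature map are data fixtures, not
code: the packaged default is generated from the synthetic class templates,
and a fixture built from real curated sHSPs can be dropped in without any
code change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, SequenceRecord, packaged_path, read_fasta

REFERENCE_ALIGNMENT = "synthetic_reference_alignment.fasta"
REFERENCE_FEATURE_MAP = "synthetic_feature_map.tsv"

STRAND_FEATURES = tuple(f"beta{i}" for i in range(2, 10))

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class ArchitectureError(ValueError):
    """Annotation failure (profile wider than sequence, bad fixture, ...)."""


@dataclass(frozen=True)
class Pssm:
    """Ungapped log-odds profile.

    ``matrix[j, a]`` is the score of residue ``AMINO_ACIDS[a]`` at column
    ``j``; unknown residues (X) score 0, the background expectation.
    ``kept_columns`` maps profile columns back to 1-based columns of the
    source alignment (columns above 50% gaps are dropped at build time).
    """

    matrix: np.ndarray
    pseudocount: float
    background: np.ndarray
    kept_columns: tuple[int, ...]

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score_window(self, residues: str, start0: int) -> float:
        total = 0.0
        for j in range(self.width):
            idx = _AA_INDEX.get(residues[start0 + j])
            if idx is not None:
                total += self.matrix[j, idx]
        return total


def build_pssm(
    alignment: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    max_gap_fraction: float = 0.5,
) -> Pssm:
    """Build a log-odds PSSM from gapped, equal-length alignment rows.

    score(col, aa) = log( ((count + pc*bg_aa) / (N + pc)) / bg_aa )
    with N the number of non-gap residues in the column.  Columns whose gap
    fraction is >= ``max_gap_fraction`` are dropped; the mapping to original
    columns is recorded in ``kept_columns``.
    """
    if not alignment:
        raise ArchitectureError("empty alignment")
    ncols = len(alignment[0])
    if any(len(row) != ncols for row in alignment):
        raise ArchitectureError("ragged alignment rows")
    if pseudocount < 0:
        raise ArchitectureError("pseudocount must be >= 0")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or not math.isclose(background.sum(), 1.0, rel_tol=1e-9):
        raise ArchitectureError("background must be 20 frequencies summing to 1")

    columns: list[np.ndarray] = []
    kept: list[int] = []
    nrows = len(alignment)
    for c in range(ncols):
        col = [row[c] for row in alignment]
        gaps = sum(1 for ch in col if ch in "-.")
        if gaps / nrows >= max_gap_fraction:
            continue
        counts = np.zeros(20)
        n = 0
        for ch in col:
            idx = _AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
                n += 1
        scores = np.log((counts + pseudocount * background) / (n + pseudocount) / background)
        columns.append(scores)
        kept.append(c + 1)
    if not columns:
        raise ArchitectureError("no columns survive the gap-fraction filter")
    return Pssm(
        matrix=np.vstack(columns),
        pseudocount=pseudocount,
        background=background,
        kept_columns=tuple(kept),
    )


def best_window(pssm: Pssm, record: SequenceRecord) -> tuple[int, float]:
    """Best ungapped placement of the profile: (1-based start, total score).

    Ties are broken toward the smallest start, so annotation is deterministic.
    """
    if record.length < pssm.width:
        raise ArchitectureError(
            f"sequence {record.id!r} (length {record.length}) shorter than "
            f"profile width {pssm.width}"
        )
    # vectorized scan: per-position score rows, summed over sliding windows
    idx = np.array([_AA_INDEX.get(ch, -1) for ch in record.residues])
    padded = np.hstack([pssm.matrix, np.zeros((pssm.width, 1))])  # X -> 0
    nwin = record.length - pssm.width + 1
    scores = np.empty(nwin)
    per_pos = padded[np.arange(pssm.width)[None, :].repeat(nwin, 0),
                     np.lib.stride_tricks.sliding_window_view(idx, pssm.width)]
    scores = per_pos.sum(axis=1)
    best0 = int(np.argmax(scores))  # argmax takes the first (= leftmost) max
    return best0 + 1, float(scores[best0])


@dataclass(frozen=True)
class RegionAnnotation:
    """N-arm / ACD / C-extension bounds plus the projected feature map."""

    sequence_id: str
    length: int
    acd_start: int
    acd_end: int
    strand_map: dict[str, tuple[int, int]]
    l57_interval: tuple[int, int]
    beta7_column: int
    acd_score: float
    #: reference column of the first L57-loop position (109 by convention)
    l57_ref_start: int = 109

    def __post_init__(self) -> None:
        if not (1 <= self.acd_start <= self.acd_end <= self.length):
            raise ArchitectureError(
                f"{self.sequence_id}: ACD bounds [{self.acd_start}, {self.acd_end}] "
                f"outside sequence of length {self.length}"
            )

    @property
    def n_arm(self) -> tuple[int, int] | None:
        """1-based N-arm interval, or None when the ACD starts at residue 1."""
        return (1, self.acd_start - 1) if self.acd_start > 1 else None

    @property
    def c_ext(self) -> tuple[int, int] | None:
        return (self.acd_end + 1, self.length) if self.acd_end < self.length else None

    def region_of(self, pos: int) -> str:
        if not 1 <= pos <= self.length:
            raise ArchitectureError(f"position {pos} outside sequence")
        if pos < self.acd_start:
            return "n_arm"
        if pos > self.acd_end:
            return "c_ext"
        return "acd"


@dataclass(frozen=True)
class Reference:
    """Bundle of the reference alignment, its ACD profile and feature map.

    ``features`` holds reference-column intervals for beta2..beta9 and L57;
    ``beta7_arg_column`` is the reference column of the conserved β7 arginine.
    ``acd_columns`` is the (start, end) reference-column interval the PSSM was
    built from.
    """

    rows: dict[str, str]
    pssm: Pssm
    acd_columns: tuple[int, int]
    features: dict[str, tuple[int, int]]
    beta7_arg_column: int

    def to_sequence_coords(self, ref_col: int, acd_start: int) -> int:
        """Project a reference column into sequence coordinates."""
        return acd_start + (ref_col - self.acd_columns[0])


def load_feature_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"column": int, "region": str, "feature": str, "marker": str})
    df = df.fillna({"feature": "none", "marker": "none"})
    required = {"column", "region", "feature"}
    if not required.issubset(df.columns):
        raise ArchitectureError(f"feature map {path} lacks columns {sorted(required)}")
    return df


def load_reference(
    alignment_path: str | Path | None = None,
    feature_map_path: str | Path | None = None,
    pseudocount: float = 1.0,
) -> Reference:
    """Load a reference fixture (packaged synthetic default) into a profile.

    The ACD profile is built from the reference columns whose ``region`` is
    ``acd``; that interval must be contiguous.
    """
    if alignment_path is None:
        alignment_path = packaged_path(REFERENCE_ALIGNMENT)
    if feature_map_path is None:
        feature_map_path = packaged_path(REFERENCE_FEATURE_MAP)
    records = read_fasta(alignment_path)
    rows = {r.id: r.residues for r in records}
    ncols = len(next(iter(rows.values())))
    if any(len(v) != ncols for v in rows.values()):
        raise ArchitectureError("reference alignment rows have unequal length")

    fmap = load_feature_map(feature_map_path)
    acd_cols = sorted(fmap.loc[fmap.region == "acd", "column"])
    if not acd_cols:
        raise ArchitectureError("feature map defines no ACD columns")
    if acd_cols != list(range(acd_cols[0], acd_cols[-1] + 1)):
        raise ArchitectureError("ACD reference columns are not contiguous")
    acd_start, acd_end = acd_cols[0], acd_cols[-1]

    features: dict[str, tuple[int, int]] = {}
    for feat in (*STRAND_FEATURES, "L57"):
        cols = sorted(fmap.loc[fmap.feature == feat, "column"])
        if not cols:
            raise ArchitectureError(f"feature map lacks feature {feat!r}")
        if cols != list(range(cols[0], cols[-1] + 1)):
            raise ArchitectureError(f"feature {feat!r} columns are not contiguous")
        if not (acd_start <= cols[0] and cols[-1] <= acd_end):
            raise ArchitectureError(f"feature {feat!r} outside the ACD interval")
        features[feat] = (cols[0], cols[-1])

    beta7_rows = fmap.loc[fmap.get("marker", "none") == "beta7_arg", "column"]
    if len(beta7_rows) != 1:
        raise ArchitectureError("feature map must mark exactly one beta7_arg column")
    beta7_col = int(beta7_rows.iloc[0])
    b7 = features["beta7"]
    if not b7[0] <= beta7_col <= b7[1]:
        raise ArchitectureError("beta7_arg marker outside the beta7 strand")

    acd_rows = [row[acd_start - 1 : acd_end] for row in rows.values()]
    pssm = build_pssm(acd_rows, pseudocount=pseudocount)
    if pssm.width != acd_end - acd_start + 1:
        # dropped columns would break the fixed-offset column projection
        raise ArchitectureError(
            "reference ACD columns must all be below the 50% gap threshold"
        )
    return Reference(
        rows=rows,
        pssm=pssm,
        acd_columns=(acd_start, acd_end),
        features=features,
        beta7_arg_column=beta7_col,
    )


def delimit_regions(record: SequenceRecord, reference: Reference) -> RegionAnnotation:
    """Annotate one sequence: ACD window, flanks, strands, L57 loop.

    The ACD interval is the best profile window; the N-arm is whatever
    precedes it and the C-terminal extension whatever follows, so the three
    regions partition the sequence exactly.
    """
    start, score = best_window(reference.pssm, record)
    acd_start = start
    acd_end = start + reference.pssm.width - 1
    strand_map = {
        feat: (
            reference.to_sequence_coords(lo, acd_start),
            reference.to_sequence_coords(hi, acd_start),
        )
        for feat, (lo, hi) in reference.features.items()
        if feat != "L57"
    }
    l57_lo, l57_hi = reference.features["L57"]
    return RegionAnnotation(
        sequence_id=record.id,
        length=record.length,
        acd_start=acd_start,
        acd_end=acd_end,
        strand_map=strand_map,
        l57_interval=(
            reference.to_sequence_coords(l57_lo, acd_start),
            reference.to_sequence_coords(l57_hi, acd_start),
        ),
        beta7_column=reference.to_sequence_coords(reference.beta7_arg_column, acd_start),
        acd_score=score,
        l57_ref_start=l57_lo,
    )
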