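# Methods

This note documents the models and numerical choices behind `shspkit`, in
the order the pipeline applies them, and ends with the simulator's scope and
known limitations.

## Pattern engine

The PROSITE-style grammar is deliberately minimal: dash-separated elements
that are a fixed residue, a residue class `[..]`, or a fixed-length wildcard
run `x` / `x(n)`. Variable-length runs `x(a,b)` and the anchors `<`/`>` are
unsupported — the sHSP signature needs only `x(9)`, and a smaller grammar is
easier to verify exhaustively. Scanning reports **all** matches, overlaps
included, in ascending start order; downstream rules use "≥ 1 hit", so
reporting everything loses nothing and drops no evidence. An `X` in a
sequence (ambiguity) matches only wildcard slots: ambiguous residues never
count as positive evidence. The scanner is validated against an independent
element-by-element enumerator over every start position.

The signature's position relative to the predicted β2–β3 strands is
recorded via the region annotation but is *not* required for a hit to count
toward classification; whether that restriction should be enforced is an
open question the data model leaves to the caller.

## Architecture annotation

The ACD is located with an ungapped log-odds position-specific scoring
matrix (PSSM) rather than a profile HMM: the placement problem here is
ungapped by construction (the domain is a fixed-width block in the reference
coordinate system), and an ungapped PSSM is deterministic and directly
testable against closed forms. Column scores are

    score(c, a) = log( ((n_ca + τ·b_a) / (N_c + τ)) / b_a )

with pseudocount τ = 1, uniform background b, and N_c the non-gap count in
column c. Columns with ≥ 50 % gaps are dropped (the kept-column map is
recorded). The best window maximizes the summed column scores; ties break
toward the smallest start so annotation is reproducible. Unknown residues
(X) score 0, the background expectation. Profile width defaults to the
ACD's 92 columns.

All coordinates are 1-based inclusive, matching how positions are printed
in the sHSP literature (L142, position 117). The reference coordinate
system is a full-length alignment — N-arm columns 1–55, ACD columns 56–147,
C-extension columns 148–160 — so the L57 loop (columns 109–121) falls inside
the ACD, as it must. β-strand intervals, the L57 loop and the β7-arginine
column live in a TSV fixture (`synthetic_feature_map.tsv`), not in code:
coordinates are data and can be recalibrated (e.g. from curated natural
sHSPs) without touching the implementation. The packaged default reference
alignment is generated from the synthetic class templates (the file name
says so); a fixture built from real sequences can be dropped in.

The N-arm is whatever precedes the best window and the C-extension whatever
follows it, so the three regions always partition the sequence exactly, and
the whole annotation is shift-equivariant by construction.

## Motif detection

CAM search is restricted to the C-terminal extension, where anchoring
modules function; windows must lie entirely inside the extension, so hits
never straddle the ACD boundary. Pair CAMs (L-X-[ILV], A-X-P, L-X-G,
L-X-A) and the triple form ([IV]-X-[ILV]-X-[ILV]) are all reported,
overlaps included; a triple never suppresses the pair motifs it contains.
Doublet (A-G / P-G) search uses the ACD plus a 10-residue flank on each
side — the markers sit in or at the edge of the domain, and the permissive
window plus the recorded region lets downstream rules tighten the criterion
later without re-scanning. Context flags record the class-A sandwich
(preceding L, following F/Y/W). The β7 residue is read at the mapped
reference column and reported descriptively (R / basic / N) rather than
judged; acidic L57-loop partners are every D/E in the mapped loop interval,
with the canonical column 117 flagged.

## Classification cascade

Rules fire in specificity order, first match wins:

1. ≥ 1 signature hit → `cyanophage_like` — the signature is the single
   most specific marker;
2. triple CAM in the extension **and** P-G doublet → `cyanobacterial_like`;
3. A-G doublet → `bacterial_class_A_like`;
4. P-G doublet → `class_B_plant_like`;
5. otherwise `unclassified`.

The A-G marker is shared with animal sHSPs, so label 3 is a sequence-type
call, not a taxonomic one. Sequences carrying both doublets have no
published tie-break; rule 3 before rule 4 is this package's documented
choice. Every result carries the hits that fired its rule, and exactly one
rule fires per sequence.

## Alignment and region extraction

Pairwise alignment is global affine-gap (Gotoh) with BLOSUM62 (loaded from
Biopython's `substitution_matrices`), gap open 10 and extend 0.5; a gap of
length k costs `open + (k−1)·extend`. Traceback ties resolve
diagonal > up > left. The multiple aligner is progressive: a guide tree
from 3-mer Jaccard distances (average linkage) and frequency-profile
merging with the same gap model. The scheme is intentionally
self-contained and fully deterministic — identical inputs give
byte-identical alignments, which the distance and tree stages rely on. It
does not attempt iterative refinement and is not a ClustalW/MAFFT
replacement for hard alignment problems.

For phylogeny, only ACD and C-extension columns are used. The concrete
rule: keep a column when ≥ 50 % of rows place an ACD or extension residue
in it, and mask any N-arm residue inside a kept column to a gap. The 50 %
occupancy threshold is this package's explicit, testable formulation of
"use only the ACD and C-terminal extension".

## Distances and BioNJ

Distances are Poisson-corrected p-distances, d = −ln(1−p), with p the
mismatch fraction over columns where both rows have residues. Saturated
pairs (p ≥ 0.95) are capped at d = 10 to keep the matrix finite; both
thresholds are parameters. The tree is built with BioNJ: standard
neighbor-joining selection (minimum Q, ties to the smallest taxon-pair
index) with the variance-weighted reduction — the new node's distances are
the λ-blend of the joined pair's, λ chosen to minimize the reduced
variance under the first-order model Var ∝ d. Negative branch-length
estimates are clamped to zero with the deficit moved to the sibling, so the
joined pair's path length is conserved. On additive matrices the method
recovers topology and branch lengths exactly; the test suite checks this on
random Yule trees and cross-checks topologies against scikit-bio's NJ.
Monophyly of a taxon set is decided by edge bipartitions (unrooted
convention), so a set and its complement give the same answer. Maximum
likelihood, rate models and branch-support statistics are out of scope; the
tree is reported fully resolved.

## The simulator, benchmark conditions, and what they show

The simulator emulates exactly the structure the analysis assumes: four
class templates over one 160-column layout (arm 1–55 ending in the double
proline, ACD 56–147 with strands/L57/β7-R/E117, extension 148–160 opening
with proline and carrying the class CAM), with the signature planted across
β2–β3 of the cyanophage template, A-G in the L…F sandwich for cyanophage
and class A, and P-G for the plant and cyanobacterial templates. Templates
derive from a common scaffold with 30 % class-specific divergence — enough
to separate the clades without saturating every between-class distance —
and are repaired after construction so each class's planted markers are its
only marker instances.

Families evolve along a planted-clade tree (one Yule subtree per class,
birth rate 1, glued to a fixed backbone). Each site substitutes with
probability μ per branch, to a uniformly random different residue; marker
columns substitute with probability ρ·μ. Branch lengths shape the tree
metric only and never the substitution count, so per-branch divergence is
exactly Binomial(L, μ) — a property the tests assert directly. The uniform
replacement model means Poisson-corrected distances are biased relative to
the true process, but monotonically so, which is sufficient for
topology-recovery benchmarks. Indels default to 0 so that truth-table
coordinates remain valid; a nonzero rate exists for aligner stress tests
only.

The benchmark conditions are 4 × 50 sequences, μ = 0.05, ρ = 0.1. Under
them, ACD placement and clade monophyly are robust (both measured at 100 %
here), but **class-label recovery is limited by marker survival, not by the
detector**: a leaf sits ~6–9 branches below its class root, so each of the
7 constrained signature columns survives with about (1 − ρμ)^8 ≈ 0.96, the
intact signature with only ≈ 0.75–0.85, and an analogous calculation
applies to the doublets and the triple CAM. Measured recovery is
accordingly ≈ 0.81–0.91: the missed sequences are ones whose diagnostic
columns genuinely mutated away, which no scanner can recover. This is a
property of the stated simulation conditions themselves; recovery
approaches 1 as ρ → 0 (full marker protection), which the test suite also
exercises.

Passing these benchmarks therefore shows that the detectors, annotator and
tree machinery are exact and deterministic on data matching their model —
fixed-width ungapped domains, markers at known reference columns, no
alignment ambiguity. It does **not** show performance on real, indel-rich
families with length-variable arms and extensions, drifted marker
positions, or compositional bias; for those, the reference fixture should
be rebuilt from curated natural sHSPs and the region-extraction and doublet
windows revisited.

## Degenerate inputs and numeric conventions

Sequences shorter than the profile are annotation errors (propagated with
the sequence id); empty extensions yield empty CAM lists, not errors;
scanning a sequence shorter than a pattern yields an empty hit list. FASTA
residues outside the 20-letter alphabet are an error in strict mode and map
to X in lenient mode, because motif semantics are undefined on ambiguity
codes. All floating-point comparisons in traceback use an absolute 1e-9
tolerance; newick round trips preserve branch lengths to 6 decimals.
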