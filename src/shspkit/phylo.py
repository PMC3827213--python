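"""Distance phylogeny: Poisson-corrected distances, BioNJ, monophyly.

The tree-building arm is BioNJ (Gascuel 1997): neighbor joining with a
first-order variance model, so that when two clusters are merged the distance
update is the variance-minimizing convex combination rather than NJ's plain
average.  On additive distance matrices BioNJ, like NJ, recovers the
generating topology and branch lengths exactly; that property anchors the
test suite.

Trees are held in dendropy (unrooted convention); newick serialization and
parsing go through it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .msa import GAP, Alignment


class PhyloError(ValueError):
    """Phylogeny failure (degenerate matrix, malformed newick, ...)."""


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances with a zero diagonal."""

    taxa: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise PhyloError("distance matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise PhyloError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise PhyloError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise PhyloError("distances must be finite and nonnegative")

    def to_phylip(self) -> str:
        """PHYLIP-style square matrix text."""
        lines = [f"{len(self.taxa)}"]
        for name, row in zip(self.taxa, self.d):
            lines.append(name + "  " + "  ".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def poisson_distance(
    alignment: Alignment, p_cap: float = 0.95, d_max: float = 10.0
) -> DistanceMatrix:
    """Poisson-corrected pairwise distances d = -ln(1 - p).

    p is the mismatch proportion over columns where both rows have residues.
    Saturated pairs (p >= ``p_cap``) are capped at ``d_max`` so the matrix
    stays finite.  A pair sharing no ungapped column is an error.
    """
    ids = alignment.ids
    if len(ids) < 2:
        raise PhyloError("need at least 2 rows for a distance matrix")
    rows = [np.frombuffer(alignment.rows[i].encode(), dtype=np.uint8) for i in ids]
    gap_codes = {ord(GAP), ord(".")}
    masks = [~np.isin(r, list(gap_codes)) for r in rows]
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = masks[i] & masks[j]
            nshared = int(shared.sum())
            if nshared == 0:
                raise PhyloError(f"rows {ids[i]!r} and {ids[j]!r} share no ungapped columns")
            p = float((rows[i][shared] != rows[j][shared]).mean())
            dij = d_max if p >= p_cap else -math.log(1.0 - p)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(tuple(ids), d)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------

@dataclass
class PhyloTree:
    """An unrooted tree with branch lengths, backed by dendropy."""

    tree: dendropy.Tree

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            t = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises assorted error types
            raise PhyloError(f"malformed newick: {exc}") from exc
        t.is_rooted = False
        return cls(t)

    @classmethod
    def read(cls, path: str | Path) -> "PhyloTree":
        return cls.from_newick(Path(path).read_text())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
        ).strip() + "\n"

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_newick())

    @property
    def taxa(self) -> set[str]:
        return {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}

    def branch_lengths(self) -> list[float]:
        return [
            e.length for e in self.tree.preorder_edge_iter()
            if e.length is not None
        ]

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf set under each edge (child side), unrooted convention."""
        out = []
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            out.append(frozenset(l.taxon.label for l in node.leaf_iter()))
        return out


def is_monophyletic(tree: PhyloTree, taxa_set: set[str]) -> bool:
    """True iff some edge bipartition separates exactly ``taxa_set``.

    Unrooted convention: a set and its complement are the same bipartition,
    so the result is symmetric under complementation.  The set must be a
    non-empty proper subset of the leaves.
    """
    leaves = tree.taxa
    taxa_set = set(taxa_set)
    unknown = taxa_set - leaves
    if unknown:
        raise PhyloError(f"unknown taxa {sorted(unknown)}")
    if not taxa_set or taxa_set == leaves:
        raise PhyloError("taxa set must be a non-empty proper subset of the leaves")
    target = frozenset(taxa_set)
    complement = frozenset(leaves - taxa_set)
    for clade in tree.bipartitions():
        if clade == target or clade == complement:
            return True
    return False


def bionj(dm: DistanceMatrix) -> PhyloTree:
    """BioNJ agglomeration of a distance matrix into an unrooted tree.

    Standard neighbor-joining selection (minimum Q criterion, ties broken by
    the smallest taxon-pair index) with BioNJ's variance-weighted reduction:
    the new node's distances are ``lambda*(d_ik - v_i) + (1-lambda)*(d_jk - v_j)``
    with lambda chosen to minimize the variance of the reduced matrix.
    Negative branch-length estimates are clamped to zero and the deficit moved
    to the sibling branch, keeping the path length between the joined taxa.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("BioNJ needs at least 3 taxa")
    D = dm.d.astype(float).copy()
    V = dm.d.astype(float).copy()  # first-order variance model: Var ~ d
    # node ids: newick fragments built bottom-up
    nodes = [f"{label}" for label in dm.taxa]
    active = list(range(n))

    def clamp_pair(vi: float, vj: float) -> tuple[float, float]:
        if vi < 0:
            vj += vi  # conserve vi + vj
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        return max(vi, 0.0), max(vj, 0.0)

    while len(active) > 3:
        r = len(active)
        # Q criterion over active nodes
        sums = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        vi = 0.5 * D[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))
        vj = D[i, j] - vi
        vi, vj = clamp_pair(vi, vj)
        # BioNJ lambda
        others = [k for k in active if k != i and k != j]
        if V[i, j] > 0:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in others) / (2 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        # reduce
        u = len(nodes)
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in others:
            D[u, k] = D[k, u] = lam * (D[i, k] - vi) + (1 - lam) * (D[j, k] - vj)
            V[u, k] = V[k, u] = lam * V[i, k] + (1 - lam) * V[j, k] - lam * (1 - lam) * V[i, j]
        nodes.append(f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g})")
        active = [k for k in active if k != i and k != j] + [u]

    i, j, k = active
    vi = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    vj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    vk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    vi, vj, vk = (max(v, 0.0) for v in (vi, vj, vk))
    newick = f"({nodes[i]}:{vi:.10g},{nodes[j]}:{vj:.10g},{nodes[k]}:{vk:.10g});"
    return PhyloTree.from_newick(newick)


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted Robinson-Foulds distance (symmetric bipartition difference)."""
    if a.taxa != b.taxa:
        raise PhyloError("trees are over different taxon sets")
    leaves = a.taxa

    def nontrivial(t: PhyloTree) -> set[frozenset[str]]:
        out = set()
        for clade in t.bipartitions():
            side = min(clade, frozenset(leaves - clade), key=lambda s: (len(s), sorted(s)))
            if 2 <= len(side) <= len(leaves) - 2:
                out.add(side)
        return out

    return len(nontrivial(a) ^ nontrivial(b))
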