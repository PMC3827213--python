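"""Poisson distances, BioNJ reconstruction, monophyly and newick I/O."""

import math
import random

import dendropy
import numpy as np
import pytest

from shspkit.msa import Alignment
from shspkit.phylo import (
    DistanceMatrix,
    PhyloError,
    PhyloTree,
    bionj,
    is_monophyletic,
    poisson_distance,
    robinson_foulds,
)

from conftest import random_protein


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def test_identical_rows_distance_zero():
    dm = poisson_distance(Alignment({"a": "MKVL", "b": "MKVL"}))
    assert dm.d[0, 1] == 0.0


def test_half_mismatch_closed_form():
    dm = poisson_distance(Alignment({"a": "MKVL", "b": "MKAA"}))
    assert dm.d[0, 1] == pytest.approx(math.log(2))


def test_saturated_pairs_capped():
    dm = poisson_distance(Alignment({"a": "MKVL", "b": "AAAA"}))  # p = 1
    assert dm.d[0, 1] == 10.0


def test_gapped_columns_excluded():
    # only columns 1 and 4 are shared; one mismatch -> p = 0.5
    dm = poisson_distance(Alignment({"a": "M--L", "b": "MKVA"}))
    assert dm.d[0, 1] == pytest.approx(math.log(2))


def test_no_shared_columns_errors():
    with pytest.raises(PhyloError, match="no ungapped"):
        poisson_distance(Alignment({"a": "M-", "b": "-K"}))


def test_distance_matrix_invariants_random(rng):
    for _ in range(20):
        n = int(rng.integers(2, 7))
        L = int(rng.integers(5, 40))
        aln = Alignment({f"s{i}": random_protein(rng, L) for i in range(n)})
        dm = poisson_distance(aln)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert np.all(dm.d >= 0)


def test_distance_matrix_validation():
    with pytest.raises(PhyloError, match="symmetric"):
        DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(PhyloError, match="diagonal"):
        DistanceMatrix(("a", "b"), np.array([[1.0, 1.0], [1.0, 0.0]]))


# ---------------------------------------------------------------------------
# BioNJ
# ---------------------------------------------------------------------------

def test_three_taxon_closed_form():
    d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
    tree = bionj(DistanceMatrix(("a", "b", "c"), d))
    lengths = {}
    for leaf in tree.tree.leaf_node_iter():
        lengths[leaf.taxon.label] = leaf.edge.length
    assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)


def test_bionj_too_few_taxa():
    with pytest.raises(PhyloError):
        bionj(DistanceMatrix(("a", "b"), np.zeros((2, 2))))


def _random_yule_tree(rng, n):
    """dendropy Yule topology with uniform random branch lengths."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=n, rng=random.Random(int(rng.integers(2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    tree.is_rooted = False
    return tree


def _additive_matrix(tree):
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(t.label for t in tree.taxon_namespace)
    n = len(labels)
    d = np.zeros((n, n))
    taxon = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxon[labels[i]], taxon[labels[j]])
    return DistanceMatrix(tuple(labels), d)


def test_additive_five_taxon_exact_recovery(rng):
    """On an additive matrix BioNJ returns the generating tree exactly,
    topology and branch lengths."""
    true = PhyloTree.from_newick("((a:0.3,b:0.4):0.25,(c:0.2,d:0.35):0.15,e:0.5);")
    dm = _additive_matrix(true.tree)
    est = bionj(dm)
    assert robinson_foulds(true, est) == 0
    # patristic distances reproduce the input matrix exactly
    back = _additive_matrix(est.tree)
    assert np.allclose(back.d, dm.d, atol=1e-9)


def test_bionj_consistency_on_random_yule_trees(rng):
    for _ in range(15):
        n = int(rng.integers(6, 13))
        true = _random_yule_tree(rng, n)
        dm = _additive_matrix(true)
        est = bionj(dm)
        assert robinson_foulds(PhyloTree(true), est) == 0
        assert all(l >= 0 for l in est.branch_lengths())


def test_bionj_agrees_with_skbio_on_additive_matrices(rng):
    """Independent cross-check: scikit-bio's neighbor joining recovers the
    same topology from the same additive matrix."""
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj

    for _ in range(5):
        true = _random_yule_tree(rng, 8)
        dm = _additive_matrix(true)
        est = bionj(dm)
        sk_tree = nj(SkDM(dm.d, ids=list(dm.taxa)))
        sk = PhyloTree.from_newick(str(sk_tree))
        assert robinson_foulds(est, sk) == 0


def test_negative_branch_lengths_clamped(rng):
    for _ in range(20):
        n = 6
        # noisy non-additive matrices can push NJ estimates negative
        base = rng.uniform(0.1, 1.0, size=(n, n))
        d = (base + base.T) / 2
        np.fill_diagonal(d, 0.0)
        est = bionj(DistanceMatrix(tuple(f"t{i}" for i in range(n)), d))
        assert all(l >= 0 for l in est.branch_lengths())
        assert est.taxa == {f"t{i}" for i in range(n)}


# ---------------------------------------------------------------------------
# monophyly
# ---------------------------------------------------------------------------

def test_single_leaf_is_monophyletic():
    t = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    for leaf in "abcde":
        assert is_monophyletic(t, {leaf})


def test_complement_symmetry():
    t = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1,e:1);")
    assert is_monophyletic(t, {"a", "b"})
    assert is_monophyletic(t, {"c", "d", "e"})  # complement of {a,b}
    assert not is_monophyletic(t, {"a", "c"})
    assert not is_monophyletic(t, {"b", "d", "e"})


def test_monophyly_errors():
    t = PhyloTree.from_newick("(a:1,b:1,c:1);")
    with pytest.raises(PhyloError):
        is_monophyletic(t, set())
    with pytest.raises(PhyloError):
        is_monophyletic(t, {"a", "b", "c"})
    with pytest.raises(PhyloError):
        is_monophyletic(t, {"z"})


def test_monophyly_equals_rooted_mrca_oracle(rng):
    """Against an independent oracle: root at an outside leaf, take the MRCA
    of the set, and ask whether its descendant leaves equal the set."""
    for _ in range(25):
        true = _random_yule_tree(rng, 10)
        t = PhyloTree(true)
        leaves = sorted(t.taxa)
        k = int(rng.integers(2, 9))
        subset = set(list(rng.choice(leaves, size=k, replace=False)))
        if subset == set(leaves):
            continue
        outside = next(l for l in leaves if l not in subset)
        oracle_tree = dendropy.Tree(true)
        out_node = oracle_tree.find_node_with_taxon_label(outside)
        oracle_tree.reroot_at_edge(out_node.edge, update_bipartitions=True)
        mrca = oracle_tree.mrca(taxon_labels=sorted(subset))
        mrca_leaves = {l.taxon.label for l in mrca.leaf_iter()} - {outside}
        assert is_monophyletic(t, subset) == (mrca_leaves == subset)


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def test_newick_round_trip_simple():
    t = PhyloTree.from_newick("(a:1,b:1,c:1);")
    t2 = PhyloTree.from_newick(t.to_newick())
    assert t2.taxa == {"a", "b", "c"}
    assert robinson_foulds(t, t2) == 0


def test_newick_round_trip_random(rng):
    for _ in range(15):
        true = PhyloTree(_random_yule_tree(rng, int(rng.integers(4, 10))))
        back = PhyloTree.from_newick(true.to_newick())
        assert robinson_foulds(true, back) == 0
        assert sorted(back.branch_lengths()) == pytest.approx(
            sorted(true.branch_lengths()), abs=1e-6
        )


def test_malformed_newick_errors():
    with pytest.raises(PhyloError):
        PhyloTree.from_newick("((a:1,b:1;")


def test_robinson_foulds_matches_dendropy(rng):
    """Sanity-check our RF against dendropy's symmetric difference."""
    from dendropy.calculate import treecompare

    for _ in range(10):
        ns = dendropy.TaxonNamespace([f"t{i}" for i in range(8)])
        rs = random.Random(int(rng.integers(2**31)))
        t1 = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=ns, num_extant_tips=8, rng=rs
        )
        t2 = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, taxon_namespace=ns, num_extant_tips=8, rng=rs
        )
        for t in (t1, t2):
            t.is_rooted = False
            t.encode_bipartitions()
        expected = treecompare.symmetric_difference(t1, t2)
        got = robinson_foulds(PhyloTree(t1), PhyloTree(t2))
        assert got == expected
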