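import numpy as np
import pytest

from cypevol.alignment import codon_alignment_from_dict
from cypevol.distances import DistanceMatrix, distance_matrix
from cypevol.trees import (bipartitions, bootstrap_support, is_monophyletic,
                           nj_build, ols_branch_lengths, path_distances,
                           root_with_outgroup)
from cypevol.validation import random_additive_tree


def dm(labels, values):
    return DistanceMatrix(labels=labels, values=np.array(values, dtype=float),
                          method="test")


def test_nj_three_taxon_exact():
    D = dm(["A", "B", "C"], [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
    tree = nj_build(D)
    lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx(0.05)
    assert lengths["B"] == pytest.approx(0.15)
    assert lengths["C"] == pytest.approx(0.25)


def test_nj_recovers_additive_four_taxon():
    # ((A:1,B:2):3,(C:4,D:5)) as unrooted additive distances
    D = dm(["A", "B", "C", "D"],
           [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]])
    tree = nj_build(D)
    P = path_distances(tree)
    for a in "ABCD":
        for b in "ABCD":
            assert P[(a, b)] == pytest.approx(D[(a, b)], abs=1e-9)


def test_nj_deterministic_under_ties():
    # fully symmetric distances: every join is tied
    n = 5
    labels = [f"L{i}" for i in range(n)]
    vals = np.full((n, n), 2.0) - 2.0 * np.eye(n)
    t1 = nj_build(dm(labels, vals))
    t2 = nj_build(dm(labels, vals))
    assert bipartitions(t1) == bipartitions(t2)


def test_nj_agrees_with_skbio():
    skbio = pytest.importorskip("skbio")
    from skbio import DistanceMatrix as SkDM
    from skbio.tree import nj as sk_nj

    rng = np.random.default_rng(3)
    tree = random_additive_tree(rng, 7)
    D = path_distances(tree)
    ours = nj_build(D)
    sk_tree = sk_nj(SkDM(D.values, ids=D.labels))
    sk_bips = set()
    all_l = frozenset(D.labels)
    ref = min(all_l)
    for node in sk_tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        side = all_l - side if ref in side else side
        if 1 < len(side) < len(all_l) - 1:
            sk_bips.add(side)
    ours_internal = {b for b in bipartitions(ours)
                     if 1 < len(b) < len(all_l) - 1}
    assert ours_internal == sk_bips


def test_is_monophyletic():
    tree = nj_build(dm(["A", "B", "C", "D"],
                       [[0, 1, 5, 5], [1, 0, 5, 5],
                        [5, 5, 0, 1], [5, 5, 1, 0]]))
    mono, _ = is_monophyletic(tree, {"A", "B"})
    assert mono
    mono2, _ = is_monophyletic(tree, {"A", "C"})
    assert not mono2


def test_ols_exact_on_additive():
    rng = np.random.default_rng(7)
    tree = random_additive_tree(rng, 6)
    D = path_distances(tree)
    fit = ols_branch_lengths(tree, D)
    assert fit.sse == pytest.approx(0.0, abs=1e-18)
    assert not fit.clamped
    # branch totals reproduce every pairwise distance
    P_tot = sum(fit.lengths.values())
    true_tot = sum(n.edge.length for n in tree.preorder_node_iter()
                   if n.edge.length is not None)
    assert P_tot == pytest.approx(true_tot)


def test_ols_negative_clamped():
    # distances implying a negative internal branch
    D = dm(["A", "B", "C", "D"],
           [[0, 2, 1, 1], [2, 0, 1, 1], [1, 1, 0, 2], [1, 1, 2, 0]])
    import dendropy
    topo = dendropy.Tree.get(data="((A:1,B:1):1,(C:1,D:1):1);",
                             schema="newick", preserve_underscores=True)
    fit = ols_branch_lengths(topo, D)
    assert all(v >= 0 for v in fit.lengths.values())


def test_bootstrap_support_perfect_signal():
    seqs = {"A": "AAAAAAAAA" * 20, "B": "AAAAAAAAG" * 20,
            "C": "CCCCCCCCC" * 20, "D": "CCCCCCCCG" * 20}
    aln = codon_alignment_from_dict(seqs)

    def build(a):
        return nj_build(distance_matrix(a, method="p"))

    tree = bootstrap_support(aln, build, n_reps=50, seed=0)
    labels = [n.label for n in tree.preorder_node_iter()
              if not n.is_leaf() and n.label is not None]
    assert labels and all(float(v) == 100.0 for v in labels)


def test_root_with_outgroup():
    rng = np.random.default_rng(11)
    tree = random_additive_tree(rng, 6)
    built = nj_build(path_distances(tree))
    rooted = root_with_outgroup(built, {"T0"})
    children = rooted.seed_node.child_nodes()
    sides = [frozenset(lf.taxon.label for lf in ch.leaf_iter())
             for ch in children]
    assert frozenset({"T0"}) in sides
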