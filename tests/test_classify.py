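import numpy as np
import pytest

from cypevol.alignment import protein_alignment_from_dict
from cypevol.classify import (assign_family_by_identity, assign_type,
                              conserved_sites, group_diagnostic_sites)
from cypevol.classify import ClassifyError
from cypevol.treeio import tree_from_string


def labeled_tree(newick):
    return tree_from_string(newick)


def test_assign_type_basic():
    # query Q sits inside a supported clade of B references
    tree = labeled_tree("(((B1:1,Q:1)95:1,B2:1)99:1,(D1:1,D2:1)99:2);")
    ref = {"B1": "B", "B2": "B", "D1": "D", "D2": "D"}
    out = assign_type(tree, ref)
    assert out == {"Q": "B"}


def test_assign_type_low_support_walks_rootward():
    # the clade (B1,Q) has support 40 -> walk up to the supported B clade
    tree = labeled_tree("(((B1:1,Q:1)40:1,B2:1)99:1,(D1:1,D2:1)99:2);")
    out = assign_type(tree, {"B1": "B", "B2": "B", "D1": "D", "D2": "D"})
    assert out["Q"] == "B"


def test_assign_type_mixed_clade_unassigned():
    # Q's first informative enclosing clade mixes B and D -> unassigned
    tree = labeled_tree("((Q:1,(B1:1,D1:1)99:1)99:1,(B2:1,D2:1)99:2);")
    out = assign_type(tree, {"B1": "B", "B2": "B", "D1": "D", "D2": "D"})
    assert out["Q"] == "unassigned"


def test_assign_type_requires_reference():
    tree = labeled_tree("((A:1,B:1):1,C:2);")
    with pytest.raises(ClassifyError):
        assign_type(tree, {})


def test_family_grouping_thresholds():
    # a/b identical; c 50% identical to them; d unrelated
    aln = protein_alignment_from_dict({
        "a": "MKLRVEWSTA",
        "b": "MKLRVEWSTA",
        "c": "MKLRVGGGGG",
        "d": "WWWWWWWWWW",
    })
    groups = assign_family_by_identity(aln, family_threshold=0.40,
                                       subfamily_threshold=0.55)
    fam, sub = groups.family, groups.subfamily
    assert fam["a"] == fam["b"] == fam["c"]
    assert fam["d"] != fam["a"]
    assert sub["a"] == sub["b"]
    assert sub["c"] != sub["a"]


def test_conserved_sites():
    aln = protein_alignment_from_dict({
        "a": "MCK", "b": "MCK", "c": "MCR", "d": "MCK"})
    sites = conserved_sites(aln, threshold=0.95)
    flagged = {s.column for s in sites if s.flagged}
    assert flagged == {1, 2}
    col3 = next(s for s in sites if s.column == 3)
    assert col3.conservation == pytest.approx(0.75)
    assert col3.modal_residue == "K"


def test_group_diagnostic_sites():
    aln = protein_alignment_from_dict({
        "b1": "MAK", "b2": "MAK", "d1": "MGK", "d2": "MGK"})
    groups = {"b1": "B", "b2": "B", "d1": "D", "d2": "D"}
    reports = group_diagnostic_sites(aln, groups)
    assert any(r.column == 2 for r in reports)
    assert not any(r.column == 1 for r in reports)
    col2 = next(r for r in reports if r.column == 2)
    assert col2.diagnostic_groups == {"B": "A", "D": "G"}
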