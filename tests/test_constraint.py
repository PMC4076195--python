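from itertools import combinations

import dendropy
import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from cypevol.alignment import codon_alignment_from_dict
from cypevol.catalog import GeneCatalog, GeneRecord
from cypevol.constraint import (ConstraintError, compare_types, estimate_f,
                                mann_whitney_u)
from cypevol.simulate import SimulationConfig, simulate_codon_sequences
from cypevol.validation import QUARTET_NEWICK, estimate_f_for_simulated_gene


def quartet():
    return dendropy.Tree.get(data=QUARTET_NEWICK, schema="newick",
                             preserve_underscores=True,
                             rooting="force-rooted")


def test_estimate_f_requires_four_sequences():
    aln = codon_alignment_from_dict({"A": "AAATTT", "B": "AAGTTT"})
    with pytest.raises(ConstraintError):
        estimate_f(aln, quartet())


def test_estimate_f_on_simulated_gene():
    f = estimate_f_for_simulated_gene(seed=0, f_true=0.25, n_codons=4000)
    assert abs(f - 0.25) < 0.06


def test_estimate_f_zero_for_fully_constrained():
    cfg = SimulationConfig(seed=1, r_S=2.5e-3, f_functional=0.0,
                           n_codons=1000)
    aln, _ = simulate_codon_sequences(quartet(), cfg)
    res = estimate_f(aln, quartet())
    assert res.f == pytest.approx(0.0, abs=1e-9)
    assert res.sum_bS > 0


def enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by full enumeration (tie-free)."""
    pooled = np.array(x + y)
    n1 = len(x)
    ranks = rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    total = 0
    ge = le = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if u >= u_obs - 1e-9:
            ge += 1
        if u <= u_obs + 1e-9:
            le += 1
    return min(1.0, 2.0 * min(ge, le) / total)


def test_mwu_exact_matches_enumeration_small():
    rng = np.random.default_rng(77)
    for n1, n2 in [(2, 3), (3, 3), (4, 5), (5, 6)]:
        x = list(rng.normal(size=n1))
        y = list(rng.normal(0.5, size=n2))
        got = mann_whitney_u(x, y, mode="exact")
        assert got.P == pytest.approx(enumeration_p(x, y), abs=1e-12)
        assert got.method == "exact"


def test_mwu_ties_fall_back_to_normal():
    with pytest.warns(UserWarning):
        got = mann_whitney_u([1.0, 2.0, 2.0], [2.0, 3.0, 4.0], mode="exact")
    assert got.method == "normal"


def test_mwu_degenerate_all_tied():
    got = mann_whitney_u([1.0, 1.0], [1.0, 1.0, 1.0])
    assert got.degenerate and got.P == 1.0


def test_mwu_matches_scipy_asymptotic():
    rng = np.random.default_rng(8)
    x = list(rng.normal(size=30))
    y = list(rng.normal(0.3, size=25))
    got = mann_whitney_u(x, y, mode="normal")
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                       use_continuity=True)
    assert got.P == pytest.approx(ref.pvalue)


def test_compare_types_splits_by_catalog():
    def rec(name, typ):
        return GeneRecord(name=name, species="human", family="1",
                          subfamily="1A", clan="1", cyp_type=typ,
                          status="functional", cluster=None, parent_gene=None)

    cat = GeneCatalog(records=[rec("b1", "B"), rec("b2", "B"),
                               rec("d1", "D"), rec("d2", "D")])
    fvals = {"b1": 0.1, "b2": 0.2, "d1": 0.3, "d2": 0.4}
    cmp = compare_types(fvals, cat)
    assert cmp.summary["x"]["n"] == 2
    assert cmp.summary["y"]["n"] == 2
    assert cmp.summary["y"]["median"] > cmp.summary["x"]["median"]
    with pytest.raises(ConstraintError):
        compare_types({"b1": 0.1}, cat)
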