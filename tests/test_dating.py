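import numpy as np
import pytest

from cypevol.dating import (DatingError, bootstrap_interval, duplication_time,
                            duplication_time_from_tree, pair_ratio,
                            pseudogenization_time)
from cypevol.simulate import SimulationConfig, two_lineage_pair
from cypevol.treeio import tree_from_string


def test_duplication_time_arithmetic():
    res = duplication_time({"x": (0.25, 0.40)}, T_cal=400.0)
    assert res.estimates["x"] == pytest.approx(400 * 0.65 / 0.40)


def test_duplication_time_youngest_conservative():
    res = duplication_time({"x": (0.3, 0.4), "y": (0.2, 0.4)}, T_cal=400.0)
    assert res.youngest == pytest.approx(600.0)
    assert res.oldest == pytest.approx(700.0)


def test_duplication_time_degenerate_lineage_dropped():
    with pytest.warns(UserWarning):
        res = duplication_time({"x": (0.3, 0.0), "y": (0.2, 0.4)}, 400.0)
    assert list(res.estimates) == ["y"]
    with pytest.raises(DatingError):
        duplication_time({"x": (0.3, 0.0)}, 400.0)


def test_pseudogenization_time_formula():
    # t = 2T (R - f) / (1 - f)
    d = pseudogenization_time(R=0.55, f=0.25, T=10.0)
    assert d.t == pytest.approx(2 * 10 * (0.55 - 0.25) / 0.75)
    assert not d.clamped


def test_pseudogenization_time_endpoints():
    assert pseudogenization_time(R=0.25, f=0.25, T=10.0).t == 0.0
    full = pseudogenization_time(R=1.0, f=0.25, T=10.0)
    assert full.raw_t == pytest.approx(20.0)
    assert full.t == 10.0 and full.clamped
    below = pseudogenization_time(R=0.1, f=0.25, T=10.0)
    assert below.t == 0.0 and below.clamped


def test_pseudogenization_time_validation():
    with pytest.raises(DatingError):
        pseudogenization_time(R=0.5, f=1.0, T=10.0)
    with pytest.raises(DatingError):
        pseudogenization_time(R=-0.1, f=0.2, T=10.0)
    with pytest.raises(DatingError):
        pseudogenization_time(R=np.inf, f=0.2, T=10.0)


def test_duplication_time_from_tree():
    # duplication at root; calibration nodes are the two cherries
    t = tree_from_string("((P1_a:0.4,P1_b:0.4):0.25,(P2_a:0.4,P2_b:0.4):0.25);")
    res = duplication_time_from_tree(
        t, {"P1_a", "P1_b", "P2_a", "P2_b"},
        {"P1_a": {"P1_a", "P1_b"}, "P2_a": {"P2_a", "P2_b"}}, T_cal=400.0)
    assert res.estimates["P1_a"] == pytest.approx(650.0)
    assert res.estimates["P2_a"] == pytest.approx(650.0)


def test_pair_ratio_requires_synonymous_signal():
    with pytest.raises(DatingError):
        pair_ratio("ATGAAA", "ATGAAA")  # dS = 0


def test_bootstrap_interval_brackets_estimate():
    cfg = SimulationConfig(seed=5, r_S=5e-3, f_functional=0.25, n_codons=2000)
    aln, _ = two_lineage_pair(cfg, T=10.0, pseudo_time=6.0)

    def est(a):
        return pseudogenization_time(pair_ratio(a.row(0), a.row(1)),
                                     f=0.25, T=10.0).t

    lo, hi = bootstrap_interval(aln, est, n_reps=100, seed=1)
    assert lo < est(aln) < hi
    assert 0.0 <= lo and hi <= 10.0
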