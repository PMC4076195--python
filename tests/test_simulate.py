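import numpy as np
import pytest
from scipy import stats

from cypevol.ng86 import STOP_CODONS, codon_index, ng86_pair
from cypevol.simulate import (RegimeSegment, SimulationConfig,
                              SimulationError, simulate_codon_sequences,
                              simulate_duplication_scenario,
                              simulate_gene_content, two_lineage_pair)
from cypevol.treeio import chronogram_from_string, tree_from_string


def test_gene_content_determinism(chronogram):
    cfg = SimulationConfig(seed=9, gain_rate=3.0, loss_rate=2.0,
                           pseudo_rate=1.0, n_root_genes=5)
    m1, t1 = simulate_gene_content(cfg, chronogram)
    m2, t2 = simulate_gene_content(cfg, chronogram)
    assert (m1.counts.values == m2.counts.values).all()
    assert t1.events.events == t2.events.events
    m3, _ = simulate_gene_content(SimulationConfig(seed=10, gain_rate=3.0,
                                                   loss_rate=2.0,
                                                   pseudo_rate=1.0,
                                                   n_root_genes=5),
                                  chronogram)
    assert not (m1.counts.values == m3.counts.values).all() or \
        len(t1.events) != 0


def test_sequence_determinism():
    cfg = SimulationConfig(seed=4, r_S=2e-3, n_codons=300)
    a1, _ = two_lineage_pair(cfg, T=20.0)
    a2, _ = two_lineage_pair(cfg, T=20.0)
    assert (a1.matrix == a2.matrix).all()


def test_no_stops_in_functional_regime():
    cfg = SimulationConfig(seed=6, r_S=5e-3, f_functional=0.5, n_codons=2000)
    aln, _ = two_lineage_pair(cfg, T=50.0)
    for i in range(aln.n_sequences):
        for codon in aln.codons(i):
            assert codon_index(codon) not in STOP_CODONS


def test_pseudo_regime_can_produce_stops():
    cfg = SimulationConfig(seed=6, r_S=5e-3, f_functional=0.25,
                           n_codons=3000)
    aln, _ = two_lineage_pair(cfg, T=50.0, pseudo_time=50.0)
    psi = aln.sequence("psi")
    stops = sum(codon_index(psi[k:k + 3]) in STOP_CODONS
                for k in range(0, len(psi), 3))
    assert stops > 0


def test_f_zero_regime_gives_negligible_dn():
    """Under f = 0, every accepted change is synonymous; dN is ~0.

    NG86's equal-weight pathway averaging can still attribute fractional
    nonsynonymous differences at codons hit twice (e.g. Leu TTA vs CTC
    has one all-synonymous and one nonsynonymous minimal pathway), so
    the estimate is negligible rather than exactly zero.
    """
    cfg = SimulationConfig(seed=2, r_S=5e-3, f_functional=0.0, n_codons=1000)
    aln, _ = two_lineage_pair(cfg, T=30.0)
    counts = ng86_pair(aln.row(0), aln.row(1))
    assert counts.Sd > 0
    assert counts.dN < 0.01 * counts.dS
    # no accepted change altered any amino acid
    from cypevol.ng86 import CODON_AA
    aa0 = [CODON_AA[codon_index(c)] for c in aln.codons(0)]
    aa1 = [CODON_AA[codon_index(c)] for c in aln.codons(1)]
    assert aa0 == aa1


def test_synonymous_divergence_linear_in_time():
    # spec-style linearity probe: dS vs path duration, R^2 > 0.99
    xs, ys = [], []
    for k, T in enumerate(np.linspace(10, 100, 10)):
        cfg = SimulationConfig(seed=100 + k, r_S=1e-3, f_functional=0.25,
                               n_codons=10000)
        aln, _ = two_lineage_pair(cfg, T=float(T))
        counts = ng86_pair(aln.row(0), aln.row(1))
        xs.append(2 * T)
        ys.append(counts.dS)
    res = stats.linregress(xs, ys)
    assert res.rvalue ** 2 > 0.99
    # slope recovers the calibrated synonymous rate
    assert res.slope == pytest.approx(1e-3, rel=0.1)


def test_event_counts_follow_waiting_time_law():
    """Chi-square GOF of loss-event occurrence against the exponential law.

    A single-copy lineage with only a loss rate can suffer 0 or 1 events
    on a branch; the Poisson/exponential waiting-time law fixes
    P(1 event) = 1 - exp(-rate * duration / 100).  1,000 replicates,
    alpha = 0.01.
    """
    c = chronogram_from_string("(A:50,B:50);")
    lam, dur = 0.8, 50.0
    p_loss = 1.0 - np.exp(-lam * dur / 100.0)
    observed = [0, 0]
    n = 1000
    for seed in range(n):
        cfg = SimulationConfig(seed=seed, gain_rate=0.0, loss_rate=lam,
                               pseudo_rate=0.0, n_root_genes=1)
        _, truth = simulate_gene_content(cfg, c)
        # branch to species A only
        k = sum(1 for e in truth.events if e.branch == frozenset({"A"}))
        assert k in (0, 1)
        observed[k] += 1
    expected = [n * (1 - p_loss), n * p_loss]
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    assert chi2 < stats.chi2.ppf(0.99, df=1)


def test_regime_segments_must_cover_branch():
    tree = tree_from_string("(a:10,b:10);")
    cfg = SimulationConfig(seed=0, n_codons=10)
    bad = {"a": [RegimeSegment(duration=4.0, f=0.5)]}
    with pytest.raises(SimulationError):
        simulate_codon_sequences(tree, cfg, regimes=bad)


def test_duplication_scenario_validation():
    cfg = SimulationConfig(seed=0, n_codons=10)
    with pytest.raises(SimulationError):
        simulate_duplication_scenario(cfg, T_dup=300.0, T_cal=400.0)
    aln, tree, truth = simulate_duplication_scenario(cfg, T_dup=650.0,
                                                     T_cal=400.0)
    assert truth.notes["expected_bpre_over_bpost"] == pytest.approx(250 / 400)
    assert sorted(aln.ids) == ["P1_a", "P1_b", "P2_a", "P2_b"]


def test_pair_pseudo_time_validation():
    cfg = SimulationConfig(seed=0, n_codons=10)
    with pytest.raises(SimulationError):
        two_lineage_pair(cfg, T=10.0, pseudo_time=11.0)
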