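"""NG86 counting against independent enumeration oracles.

The oracle translates codons with biopython's codon table (an
independent statement of the genetic code) and recomputes site counts
and pathway-averaged differences from first principles, without touching
the package's lookup tables.
"""

from itertools import permutations, product

import numpy as np
import pytest
from Bio.Data.CodonTable import standard_dna_table

from cypevol.ng86 import (CodonPairCounts, corrected_distance, ng86_pair,
                          ng86_site_counts)

NUCS = "ACGT"
STOPS = set(standard_dna_table.stop_codons)          # {'TAA', 'TAG', 'TGA'}
SENSE = [c for c in ("".join(t) for t in product(NUCS, repeat=3))
         if c not in STOPS]


def oracle_aa(codon):
    return "*" if codon in STOPS else standard_dna_table.forward_table[codon]


def oracle_sites(codon):
    s = n = 0.0
    for pos in range(3):
        for alt in NUCS:
            if alt == codon[pos]:
                continue
            other = codon[:pos] + alt + codon[pos + 1:]
            if other in STOPS:
                continue
            if oracle_aa(other) == oracle_aa(codon):
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_diffs(a, b):
    diff = [p for p in range(3) if a[p] != b[p]]
    if not diff:
        return 0.0, 0.0
    clean, blocked = [], []
    for order in permutations(diff):
        cur, sd, nd, through_stop = a, 0.0, 0.0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOPS:
                through_stop = True
            if oracle_aa(cur) == oracle_aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (blocked if through_stop else clean).append((sd, nd))
    paths = clean or blocked
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


def test_site_counts_all_61_sense_codons():
    for codon in SENSE:
        got = ng86_site_counts(codon)
        want = oracle_sites(codon)
        assert got == pytest.approx(want), codon


def test_known_site_counts():
    assert ng86_site_counts("TTT") == pytest.approx((1 / 3, 8 / 3))
    assert ng86_site_counts("CTA")[0] == pytest.approx(4 / 3)
    assert ng86_site_counts("ATG") == pytest.approx((0.0, 3.0))


def test_pair_differences_200_random_pairs():
    rng = np.random.default_rng(42)
    for _ in range(200):
        a, b = (SENSE[i] for i in rng.integers(0, len(SENSE), size=2))
        counts = ng86_pair(a, b, correction="none")
        sd, nd = oracle_diffs(a, b)
        assert counts.Sd == pytest.approx(sd), (a, b)
        assert counts.Nd == pytest.approx(nd), (a, b)
        sa, na = oracle_sites(a)
        sb, nb = oracle_sites(b)
        assert counts.S == pytest.approx((sa + sb) / 2)
        assert counts.N == pytest.approx((na + nb) / 2)


def test_jc_correction_values():
    assert corrected_distance(0.0) == 0.0
    assert corrected_distance(0.3) == pytest.approx(0.383119, abs=1e-6)
    assert corrected_distance(0.75) == np.inf
    assert corrected_distance(0.3, "none") == 0.3


def test_pair_skips_stops_and_gaps():
    # middle codon has a stop in one partner; last codon is gapped
    counts = ng86_pair("AAATAAAAA", "AAAAAAA--")
    assert counts.skipped_stop_codons == 1
    assert counts.n_codons == 1
    assert counts.Sd == 0.0 and counts.Nd == 0.0


def test_identical_sequences_zero():
    counts = ng86_pair("ATGAAATTT", "ATGAAATTT")
    assert counts.dS == 0.0 and counts.dN == 0.0


def test_saturation_flag():
    c = CodonPairCounts(S=10, N=20, Sd=8, Nd=2, n_codons=10)
    assert c.saturated
    assert c.dS == np.inf
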