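"""Nei–Gojobori (1986) counting of synonymous and nonsynonymous sites
and differences, with Jukes–Cantor distance correction.

Site counting: each of the nine single-nucleotide changes of a codon
carries weight 1/3 of a site; changes creating a stop codon are dropped,
so a codon's synonymous plus nonsynonymous sites total 3 minus one third
per stop-adjacent change.  (Weighting by the number of non-stop changes
instead would over-count nonsynonymous sites at stop-adjacent positions
and bias dN/dS below its generative value.)  Differences between codons that
differ at 2–3 positions are averaged with equal weight over all minimal
substitution pathways; pathways passing through a stop codon are
excluded unless every pathway does.

All per-codon and per-codon-pair quantities are precomputed into lookup
tables over the 64 codons, so whole-alignment pair counts are vectorized
array sums.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

NUCS = "ACGT"
NUC_INDEX = {n: i for i, n in enumerate(NUCS)}

# Standard genetic code over codon index 16*n0 + 4*n1 + n2 (ACGT digits).
_BASES = "TCAG"
_AMINO = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")


def _code_table() -> list[str]:
    table = [""] * 64
    k = 0
    for n0 in _BASES:
        for n1 in _BASES:
            for n2 in _BASES:
                idx = 16 * NUC_INDEX[n0] + 4 * NUC_INDEX[n1] + NUC_INDEX[n2]
                table[idx] = _AMINO[k]
                k += 1
    return table


CODON_AA = _code_table()          # codon index -> amino acid letter, '*' = stop
STOP_CODONS = frozenset(i for i in range(64) if CODON_AA[i] == "*")


def codon_index(codon: str) -> int:
    """Index of an unambiguous codon, or -1 if gapped/ambiguous."""
    if len(codon) != 3:
        raise ValueError(f"not a codon: {codon!r}")
    idx = 0
    for ch in codon:
        if ch not in NUC_INDEX:
            return -1
        idx = idx * 4 + NUC_INDEX[ch]
    return idx


def index_codon(idx: int) -> str:
    return NUCS[idx // 16] + NUCS[(idx // 4) % 4] + NUCS[idx % 4]


def _neighbors(idx: int, pos: int) -> list[int]:
    """The three codons differing from idx only at codon position pos."""
    digits = [idx // 16, (idx // 4) % 4, idx % 4]
    out = []
    for alt in range(4):
        if alt != digits[pos]:
            d = list(digits)
            d[pos] = alt
            out.append(16 * d[0] + 4 * d[1] + d[2])
    return out


def _site_counts(idx: int) -> tuple[float, float]:
    if idx in STOP_CODONS:
        raise ValueError(f"stop codon {index_codon(idx)} has no site counts")
    aa = CODON_AA[idx]
    s = 0.0
    n = 0.0
    for pos in range(3):
        for j in _neighbors(idx, pos):
            if j in STOP_CODONS:
                continue  # stop-creating changes drop out of both counts
            if CODON_AA[j] == aa:
                s += 1.0 / 3.0
            else:
                n += 1.0 / 3.0
    return s, n


def ng86_site_counts(codon: str) -> tuple[float, float]:
    """(synonymous sites, nonsynonymous sites) for one sense codon."""
    idx = codon_index(codon)
    if idx < 0:
        raise ValueError(f"ambiguous codon {codon!r}")
    return _site_counts(idx)


def _pathway_differences(a: int, b: int) -> tuple[float, float]:
    """Mean (syn diffs, nonsyn diffs) over minimal pathways between codons."""
    diff_pos = [p for p in range(3)
                if (a // (4 ** (2 - p))) % 4 != (b // (4 ** (2 - p))) % 4]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    clean: list[tuple[float, float]] = []
    blocked: list[tuple[float, float]] = []
    b_digits = [b // 16, (b // 4) % 4, b % 4]
    for order in permutations(diff_pos):
        cur = a
        sd = nd = 0.0
        through_stop = False
        for pos in order:
            digits = [cur // 16, (cur // 4) % 4, cur % 4]
            digits[pos] = b_digits[pos]
            nxt = 16 * digits[0] + 4 * digits[1] + digits[2]
            if CODON_AA[nxt] == "*":
                through_stop = True
            if CODON_AA[cur] == CODON_AA[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        (blocked if through_stop else clean).append((sd, nd))
    paths = clean if clean else blocked
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _build_tables():
    s_sites = np.full(64, np.nan)
    n_sites = np.full(64, np.nan)
    for i in range(64):
        if i not in STOP_CODONS:
            s_sites[i], n_sites[i] = _site_counts(i)
    sd = np.full((64, 64), np.nan)
    nd = np.full((64, 64), np.nan)
    for i in range(64):
        if i in STOP_CODONS:
            continue
        for j in range(64):
            if j in STOP_CODONS:
                continue
            sd[i, j], nd[i, j] = _pathway_differences(i, j)
    return s_sites, n_sites, sd, nd


S_SITES, N_SITES, SD_TABLE, ND_TABLE = _build_tables()


@dataclass
class CodonPairCounts:
    """NG86 counts and distances for one sequence pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    n_codons: int
    correction: str = "jukes_cantor"
    skipped_stop_codons: int = 0

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else np.nan

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else np.nan

    @property
    def dS(self) -> float:
        return corrected_distance(self.pS, self.correction)

    @property
    def dN(self) -> float:
        return corrected_distance(self.pN, self.correction)

    @property
    def saturated(self) -> bool:
        return any(np.isfinite(p) and p >= 0.75 for p in (self.pS, self.pN)) \
            if self.correction == "jukes_cantor" else False


def corrected_distance(p: float, correction: str = "jukes_cantor") -> float:
    """Distance from a proportion of differences (JC inflates, none passes through)."""
    if not np.isfinite(p):
        return np.nan
    if correction == "none":
        return p
    if correction != "jukes_cantor":
        raise ValueError(f"unknown correction {correction!r}")
    if p >= 0.75:
        return np.inf
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index array for an in-frame sequence; -1 marks gapped/ambiguous."""
    if len(seq) % 3:
        raise ValueError("sequence length not divisible by 3")
    n = len(seq) // 3
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        out[i] = codon_index(seq[3 * i:3 * i + 3])
    return out


def ng86_pair(a: str, b: str, correction: str = "jukes_cantor") -> CodonPairCounts:
    """NG86 counts for a pair of in-frame aligned sequences.

    Codons where either partner is gapped/ambiguous are skipped (pairwise
    deletion at codon resolution); codon pairs involving a stop codon are
    skipped and tallied in ``skipped_stop_codons``.
    """
    ia, ib = encode_codons(a), encode_codons(b)
    if ia.shape != ib.shape:
        raise ValueError("length mismatch")
    ok = (ia >= 0) & (ib >= 0)
    stop_list = np.array(sorted(STOP_CODONS))
    is_stop = np.isin(ia, stop_list) | np.isin(ib, stop_list)
    skipped = int((ok & is_stop).sum())
    use = ok & ~is_stop
    ca, cb = ia[use], ib[use]
    S = 0.5 * (S_SITES[ca].sum() + S_SITES[cb].sum())
    N = 0.5 * (N_SITES[ca].sum() + N_SITES[cb].sum())
    Sd = SD_TABLE[ca, cb].sum()
    Nd = ND_TABLE[ca, cb].sum()
    return CodonPairCounts(S=float(S), N=float(N), Sd=float(Sd), Nd=float(Nd),
                           n_codons=int(use.sum()), correction=correction,
                           skipped_stop_codons=skipped)
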