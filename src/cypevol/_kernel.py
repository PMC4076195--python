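"""Inner loop of the codon-evolution simulator.

Applies a pre-drawn stream of candidate point mutations to a codon-index
sequence under the acceptance-probability model: synonymous candidates
are always accepted, nonsynonymous candidates with probability f, and
candidates creating stop codons are rejected in functional regimes and
accepted in pseudogene regimes.  The loop is compiled with numba when
available; the fallback is the same code interpreted, so results are
bit-identical either way.
"""

from __future__ import annotations

import numpy as np

from .ng86 import CODON_AA, STOP_CODONS

AA_CODE = np.array([ord(a) for a in CODON_AA], dtype=np.int64)
IS_STOP = np.array([i in STOP_CODONS for i in range(64)], dtype=np.bool_)


def _apply_events(seq, sites, alts, accept_u, f, pseudo, aa_code, is_stop):
    n = sites.shape[0]
    for k in range(n):
        site = sites[k]
        ci = site // 3
        pos = site % 3
        codon = seq[ci]
        if pos == 0:
            digit, unit = codon // 16, 16
        elif pos == 1:
            digit, unit = (codon // 4) % 4, 4
        else:
            digit, unit = codon % 4, 1
        # the alts[k]-th (0..2) nucleotide different from the current one
        new_digit = alts[k] if alts[k] < digit else alts[k] + 1
        new_codon = codon + (new_digit - digit) * unit
        if pseudo:
            seq[ci] = new_codon
            continue
        if is_stop[new_codon]:
            continue
        if aa_code[new_codon] == aa_code[codon]:
            seq[ci] = new_codon
        elif accept_u[k] < f:
            seq[ci] = new_codon
    return seq


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _apply_events = njit(cache=False)(_apply_events)
except ImportError:  # pragma: no cover
    pass


def evolve_branch(seq: np.ndarray, duration: float, mutation_rate: float,
                  f: float, pseudo: bool, rng: np.random.Generator) -> np.ndarray:
    """Evolve a codon-index sequence in place along one branch segment.

    ``mutation_rate`` is the candidate rate per nucleotide site per unit
    time (each of the 3 alternative bases proposed at rate/3); with this
    parameterization the realized synonymous rate per synonymous site
    equals ``mutation_rate`` in expectation.
    """
    if duration < 0:
        raise ValueError("negative branch duration")
    n_nt = 3 * seq.shape[0]
    n_events = rng.poisson(n_nt * mutation_rate * duration)
    if n_events == 0:
        return seq
    sites = rng.integers(0, n_nt, size=n_events)
    alts = rng.integers(0, 3, size=n_events)
    accept_u = rng.random(n_events)
    return _apply_events(seq, sites, alts, accept_u, float(f), bool(pseudo),
                         AA_CODE, IS_STOP)


def random_sense_sequence(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random codon-index sequence over the 61 sense codons."""
    sense = np.array([i for i in range(64) if not IS_STOP[i]], dtype=np.int64)
    return sense[rng.integers(0, sense.shape[0], size=n_codons)]
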