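"""Jones–Taylor–Thornton (JTT) amino-acid replacement model.

The 190 symmetric exchangeabilities and 20 stationary frequencies below
are the published JTT constants (Jones, Taylor & Thornton 1992) in the
form conventionally distributed with phylogenetics software (lower
triangle, column-major, amino-acid order ``ARNDCQEGHILKMFPSTWYV``).  The
instantaneous rate matrix is normalized to one expected replacement per
site per unit time, so the model's branch lengths are substitutions/site.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import expm

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

_EXCHANGE_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54,
    15, 194, 378, 475, 9, 11, 298, 45, 16, 113, 310, 29,
    137, 328, 22, 38, 646, 44, 5, 74, 101, 64, 126, 20,
    17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10,
    15, 503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11,
    7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5,
    59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209,
    62, 323, 26, 597, 9, 72, 292, 43, 4, 164, 53, 51,
    18, 24, 20, 119, 26, 12, 9, 181, 18, 5, 18, 30,
    32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46,
    8, 573, 11, 229, 21, 479, 89, 10, 40, 245, 9, 32,
    961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4,
    21, 47, 103, 10, 8, 14, 43, 16, 29, 226, 24, 18,
    323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23,
    477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]

FREQUENCIES = np.array([
    0.0767479233, 0.0516909483, 0.0426449574, 0.0515439485,
    0.0198029802, 0.0407519592, 0.0618299382, 0.0731519268,
    0.0229439771, 0.0537609462, 0.0919039081, 0.0586759413,
    0.0238259762, 0.0401259599, 0.0509009491, 0.0687649312,
    0.0585649414, 0.0142609857, 0.0321019679, 0.0660049340,
])
FREQUENCIES = FREQUENCIES / FREQUENCIES.sum()


def exchangeability_matrix() -> np.ndarray:
    """Symmetric 20x20 exchangeability matrix (zero diagonal)."""
    S = np.zeros((20, 20))
    k = 0
    for j in range(19):          # column-major lower triangle
        for i in range(j + 1, 20):
            S[i, j] = S[j, i] = _EXCHANGE_LOWER[k]
            k += 1
    return S


@lru_cache(maxsize=1)
def rate_matrix() -> np.ndarray:
    """JTT instantaneous rate matrix Q, normalized to 1 sub/site/unit time."""
    S = exchangeability_matrix()
    Q = S * FREQUENCIES[np.newaxis, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -(FREQUENCIES * np.diag(Q)).sum()
    return Q / scale


@lru_cache(maxsize=None)
def transition_matrix(t: float) -> np.ndarray:
    """P(t) = expm(Q t); row i gives replacement probabilities from residue i."""
    if t < 0:
        raise ValueError("negative time")
    return expm(rate_matrix() * t)
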