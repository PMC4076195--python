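"""Pairwise evolutionary distances under explicit gap policies.

Implements the distances used throughout the pipeline: nucleotide
p-distance, protein JTT distance (one-parameter maximum likelihood under
the JTT replacement matrix), amino-acid identity, and NG86 synonymous /
nonsynonymous distances (delegated to :mod:`cypevol.ng86`).

The gap policy mirrors common practice: alignment columns where more
than ``max_gap_fraction`` of sequences are gapped are removed up front;
remaining missing data is handled per pair ("pairwise" deletion) or by
dropping any column with missing data anywhere ("complete" deletion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from . import jtt, ng86
from .alignment import Alignment, CodonAlignment

JTT_MAX_DISTANCE = 10.0


class DistanceError(ValueError):
    pass


@dataclass(frozen=True)
class SiteFilterPolicy:
    """Column-exclusion and missing-data policy."""

    max_gap_fraction: float = 0.20
    deletion_mode: str = "pairwise"   # or "complete"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_gap_fraction <= 1.0:
            raise ValueError("max_gap_fraction outside [0, 1]")
        if self.deletion_mode not in ("pairwise", "complete"):
            raise ValueError(f"unknown deletion mode {self.deletion_mode!r}")


DEFAULT_POLICY = SiteFilterPolicy()


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with method/policy metadata."""

    labels: list[str]
    values: np.ndarray
    method: str
    policy: SiteFilterPolicy = DEFAULT_POLICY
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DistanceError("label/matrix shape mismatch")
        if not np.allclose(np.diag(self.values), 0.0, equal_nan=True):
            raise DistanceError("nonzero diagonal")
        finite = np.isfinite(self.values)
        if not np.allclose(self.values[finite], self.values.T[finite]):
            raise DistanceError("matrix not symmetric")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    @property
    def n(self) -> int:
        return len(self.labels)

    def is_finite(self) -> bool:
        return bool(np.isfinite(self.values).all())

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"# method: {self.method}",
            f"# max_gap_fraction: {self.policy.max_gap_fraction}",
            f"# deletion_mode: {self.policy.deletion_mode}",
            "\t".join([""] + self.labels),
        ]
        for lab, row in zip(self.labels, self.values):
            lines.append("\t".join([lab] + [f"{v:.10g}" for v in row]))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        meta = {}
        rows = []
        labels = []
        header: list[str] | None = None
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if header is None:
                header = parts[1:]
                continue
            labels.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
        if header is None:
            raise DistanceError(f"{path}: no header row")
        policy = SiteFilterPolicy(
            max_gap_fraction=float(meta.get("max_gap_fraction", 0.2)),
            deletion_mode=meta.get("deletion_mode", "pairwise"),
        )
        return cls(labels=labels, values=np.array(rows),
                   method=meta.get("method", "unknown"), policy=policy)


def filter_columns(aln: Alignment,
                   policy: SiteFilterPolicy = DEFAULT_POLICY) -> Alignment:
    """Drop columns whose gap fraction strictly exceeds the policy maximum.

    The returned alignment's ``column_positions`` maps kept columns back
    to 1-based positions in the input.
    """
    if aln.n_sequences == 0 or aln.n_columns == 0:
        raise DistanceError("empty alignment")
    gap_frac = (aln.matrix == "-").mean(axis=0)
    keep = gap_frac <= policy.max_gap_fraction
    return aln.subset_columns(keep)


def _comparable_mask(aln: Alignment, i: int, j: int,
                     policy: SiteFilterPolicy) -> np.ndarray:
    missing = aln.is_missing()
    if policy.deletion_mode == "complete":
        return ~missing.any(axis=0)
    return ~(missing[i] | missing[j])


def p_distance(aln: Alignment, i: int, j: int,
               policy: SiteFilterPolicy = DEFAULT_POLICY) -> float:
    """Proportion of differing sites among comparable sites; NaN if none."""
    mask = _comparable_mask(aln, i, j, policy)
    n = int(mask.sum())
    if n == 0:
        return np.nan
    diffs = int((aln.matrix[i, mask] != aln.matrix[j, mask]).sum())
    return diffs / n


def identity_fraction(aln: Alignment, i: int, j: int,
                      policy: SiteFilterPolicy = DEFAULT_POLICY) -> float:
    p = p_distance(aln, i, j, policy)
    return np.nan if not np.isfinite(p) else 1.0 - p


def jtt_distance(aln: Alignment, i: int, j: int,
                 policy: SiteFilterPolicy = DEFAULT_POLICY) -> float:
    """ML distance (substitutions/site) under the JTT replacement matrix.

    Maximizes the likelihood of the observed residue pairs over a single
    divergence parameter t; returns ``inf`` (saturation) if the optimum
    hits the upper bound of 10 substitutions/site.
    """
    mask = _comparable_mask(aln, i, j, policy)
    a = aln.matrix[i, mask]
    b = aln.matrix[j, mask]
    # Discard residues outside the 20-letter alphabet.
    valid = np.isin(a, list(jtt.AA_ORDER)) & np.isin(b, list(jtt.AA_ORDER))
    a, b = a[valid], b[valid]
    if a.size == 0:
        raise DistanceError("no comparable sites")
    ia = np.array([jtt.AA_INDEX[x] for x in a])
    ib = np.array([jtt.AA_INDEX[x] for x in b])
    counts = np.zeros((20, 20))
    np.add.at(counts, (ia, ib), 1.0)
    if (ia == ib).all():
        return 0.0

    log_pi = np.log(jtt.FREQUENCIES)

    def negloglik(t: float) -> float:
        P = jtt.transition_matrix(float(t))
        with np.errstate(divide="ignore"):
            ll = counts * (log_pi[:, None] + np.log(P))
        return -np.nansum(ll)

    res = minimize_scalar(negloglik, bounds=(1e-9, JTT_MAX_DISTANCE),
                          method="bounded", options={"xatol": 1e-6})
    t = float(res.x)
    if t >= JTT_MAX_DISTANCE - 1e-3:
        warnings.warn("JTT distance saturated at optimizer bound")
        return np.inf
    return t


def _pair_fn(method: str, correction: str):
    if method == "p":
        return lambda aln, i, j, pol: p_distance(aln, i, j, pol)
    if method == "jtt":
        return lambda aln, i, j, pol: jtt_distance(aln, i, j, pol)
    if method in ("dS", "dN"):
        def fn(aln, i, j, pol):
            mask = _comparable_mask(aln, i, j, pol)
            # NG86 works on whole codons: keep codons whose 3 columns survive.
            keep = mask.reshape(-1, 3).all(axis=1)
            cols = np.repeat(keep, 3)
            counts = ng86.ng86_pair(
                "".join(aln.matrix[i, cols]),
                "".join(aln.matrix[j, cols]),
                correction=correction,
            )
            return counts.dS if method == "dS" else counts.dN
        return fn
    raise DistanceError(f"unknown method {method!r}")


def distance_matrix(aln: Alignment, method: str = "p",
                    policy: SiteFilterPolicy = DEFAULT_POLICY,
                    prefilter: bool = True,
                    correction: str = "jukes_cantor") -> DistanceMatrix:
    """All-pairs distance matrix (methods: p, jtt, dS, dN)."""
    work = filter_columns(aln, policy) if prefilter else aln
    if method in ("dS", "dN") and not isinstance(aln, CodonAlignment):
        raise DistanceError("dS/dN require a codon alignment")
    if method in ("dS", "dN") and prefilter:
        # keep frame: drop whole codons with any filtered column
        kept = set(work.column_positions.tolist())
        keep_codon = np.array([
            all(3 * c + k + 1 in kept for k in range(3))
            for c in range(aln.n_columns // 3)
        ])
        cols = np.repeat(keep_codon, 3)
        work = aln.subset_columns(cols)
    n = work.n_sequences
    fn = _pair_fn(method, correction)
    values = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            d = fn(work, i, j, policy)
            values[i, j] = values[j, i] = d
            comp[i, j] = comp[j, i] = int(
                _comparable_mask(work, i, j, policy).sum())
    if np.isnan(values).any():
        warnings.warn("undefined distances present (no comparable sites)")
    return DistanceMatrix(labels=list(work.ids), values=values, method=method,
                          policy=policy, comparable_sites=comp)
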