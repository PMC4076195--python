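"""Molecular-clock dating of gene duplications and pseudogenizations.

Duplication nodes are dated by branch-length ratios against a species
calibration: if the path from the calibration split to a tip represents
T_cal myr of clock-like evolution, the duplication age on a lineage is
T_cal x (b_pre + b_post) / b_post, where b_pre runs from the duplication
node to the calibration node and b_post from there to the tip.  Several
tip lineages give several estimates; the youngest is the conservative
choice reported.

Pseudogenization is dated from the mixture of constrained and neutral
evolution a dead gene accumulates.  Over a pair (pseudogene vs
functional ortholog) separated by total time 2T, nonsynonymous changes
accrue at fraction f of the synonymous rate while the gene works and at
the full rate for the time t since it died, so the observed ratio
R = dN/dS satisfies R = (f(2T - t) + t) / 2T, giving
t = 2T (R - f) / (1 - f).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import ng86


class DatingError(ValueError):
    pass


@dataclass
class DuplicationDatingResult:
    """Per-lineage duplication-age estimates (mya) and the conservative pick."""

    estimates: dict[str, float]
    T_cal: float

    @property
    def youngest(self) -> float:
        return min(self.estimates.values())

    @property
    def oldest(self) -> float:
        return max(self.estimates.values())


def duplication_time(lineages: dict[str, tuple[float, float]],
                     T_cal: float) -> DuplicationDatingResult:
    """Date a duplication from (b_pre, b_post) branch lengths per lineage.

    ``lineages`` maps a lineage name to (b_pre, b_post) in
    substitutions/site.  Lineages with b_post = 0 are dropped with a
    warning (the clock cannot be calibrated on them).
    """
    if T_cal <= 0:
        raise DatingError("calibration time must be positive")
    estimates: dict[str, float] = {}
    for name, (b_pre, b_post) in lineages.items():
        if b_pre < 0 or b_post < 0:
            raise DatingError(f"{name}: negative branch length")
        if b_post == 0:
            warnings.warn(f"lineage {name}: b_post = 0, estimate undefined")
            continue
        estimates[name] = T_cal * (b_pre + b_post) / b_post
    if not estimates:
        raise DatingError("no lineage with usable calibration branch")
    return DuplicationDatingResult(estimates=estimates, T_cal=T_cal)


@dataclass
class PseudogeneDating:
    """Pseudogenization-time estimate from the dN/dS mixture."""

    R: float
    f: float
    T: float
    t: float
    raw_t: float
    clamped: bool


def pseudogenization_time(R: float, f: float, T: float) -> PseudogeneDating:
    """t = 2T (R - f) / (1 - f), clamped into [0, T] with a flag.

    Endpoints: R = f gives t = 0 (no relaxation); R = 1 gives a raw
    estimate of 2T (neutral over the whole pair path), clamped to T.
    """
    if not 0.0 <= f < 1.0:
        raise DatingError("functional dN/dS f must be in [0, 1)")
    if R < 0:
        raise DatingError("R must be nonnegative")
    if not np.isfinite(R):
        raise DatingError("R undefined (dS = 0?)")
    if T <= 0:
        raise DatingError("divergence time must be positive")
    raw = 2.0 * T * (R - f) / (1.0 - f)
    t = min(max(raw, 0.0), T)
    return PseudogeneDating(R=R, f=f, T=T, t=t, raw_t=raw,
                            clamped=not (0.0 <= raw <= T))


def duplication_time_from_tree(tree, dup_clade: set[str],
                               calibrations: dict[str, set[str]],
                               T_cal: float) -> DuplicationDatingResult:
    """Extract (b_pre, b_post) per tip lineage from a gene tree and date.

    ``dup_clade`` is the leaf set under the duplication node;
    ``calibrations`` maps tip label -> leaf set under that tip's
    calibration (species-split) node.  b_pre is the path length from the
    duplication node to the calibration node, b_post from there to the
    tip; both are sums of branch lengths on the rooted tree.
    """
    from .trees import leaf_sets

    sets = leaf_sets(tree)
    by_set = {}
    for node, s in sets.items():
        by_set.setdefault(s, node)
    dup_node = by_set.get(frozenset(dup_clade))
    if dup_node is None:
        raise DatingError(f"no node with clade {sorted(dup_clade)}")

    def path_up(descendant, ancestor) -> float:
        total = 0.0
        node = descendant
        while node is not ancestor:
            if node.parent_node is None:
                raise DatingError("calibration node not ancestral to tip")
            total += node.edge.length or 0.0
            node = node.parent_node
        return total

    leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
    lineages: dict[str, tuple[float, float]] = {}
    for tip, cal_clade in calibrations.items():
        cal_node = by_set.get(frozenset(cal_clade))
        if cal_node is None:
            raise DatingError(f"no calibration node {sorted(cal_clade)}")
        b_post = path_up(leaves[tip], cal_node)
        b_pre = path_up(cal_node, dup_node)
        lineages[tip] = (b_pre, b_post)
    return duplication_time(lineages, T_cal)


def bootstrap_interval(aln, estimator, n_reps: int = 200,
                       seed: int = 0) -> tuple[float, float]:
    """2.5%-97.5% percentile interval of a column-bootstrap estimator.

    ``estimator(alignment) -> float``; codon alignments are resampled by
    codon to preserve frame.
    """
    from .alignment import CodonAlignment

    rng = np.random.default_rng(seed)
    block = 3 if isinstance(aln, CodonAlignment) else 1
    n_units = aln.n_columns // block
    vals = []
    for _ in range(n_reps):
        pick = rng.integers(0, n_units, size=n_units)
        cols = (pick[:, None] * block + np.arange(block)[None, :]).ravel()
        rep = type(aln)(ids=list(aln.ids), matrix=aln.matrix[:, cols])
        try:
            vals.append(estimator(rep))
        except (DatingError, ValueError):
            continue
    if not vals:
        raise DatingError("all bootstrap replicates failed")
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return float(lo), float(hi)


def pair_ratio(a: str, b: str, correction: str = "jukes_cantor") -> float:
    """R = dN/dS for a pair of in-frame aligned sequences (NG86)."""
    counts = ng86.ng86_pair(a, b, correction=correction)
    dS = counts.dS
    dN = counts.dN
    if not np.isfinite(dS) or dS <= 0:
        raise DatingError("dS undefined or zero; R not computable")
    return dN / dS
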