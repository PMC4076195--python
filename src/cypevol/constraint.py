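"""Per-gene functional constraint and the B-vs-D comparison.

The constraint statistic for a gene is f = sum(bN) / sum(bS), the ratio
of nonsynonymous to synonymous substitutions summed over the branches of
a fixed 4-taxon species tree (gene tree assumed equal to the species
tree, as appropriate for single-copy primate orthologs).  Branch values
come from independent ordinary-least-squares fits of the NG86 dN and dS
distance matrices on that topology.  The degree of functional constraint
is 1 - f.  Group differences in f between biosynthesis-type (B) and
detoxification-type (D) genes are tested with the Mann-Whitney U test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import stats

from .alignment import CodonAlignment
from .catalog import GeneCatalog
from .distances import SiteFilterPolicy, DEFAULT_POLICY, distance_matrix
from .trees import ols_branch_lengths


class ConstraintError(ValueError):
    pass


@dataclass
class ConstraintResult:
    """OLS-fitted per-branch substitution counts and f for one gene."""

    gene: str
    bS: dict[frozenset, float]
    bN: dict[frozenset, float]
    f: float
    clamped_branches: int = 0

    @property
    def constraint(self) -> float:
        return 1.0 - self.f

    @property
    def sum_bS(self) -> float:
        return float(sum(self.bS.values()))

    @property
    def sum_bN(self) -> float:
        return float(sum(self.bN.values()))


def estimate_f(aln: CodonAlignment, topology: dendropy.Tree,
               gene: str = "", policy: SiteFilterPolicy = DEFAULT_POLICY,
               correction: str = "jukes_cantor") -> ConstraintResult:
    """Fit dN and dS branch lengths on a fixed topology and form f.

    Negative OLS branch lengths are clamped to zero before summation.
    Raises when the synonymous total is zero (f undefined).
    """
    if aln.n_sequences != 4:
        raise ConstraintError("constraint estimation expects 4 sequences")
    dn = distance_matrix(aln, method="dN", policy=policy, correction=correction)
    ds = distance_matrix(aln, method="dS", policy=policy, correction=correction)
    fit_n = ols_branch_lengths(topology, dn)
    fit_s = ols_branch_lengths(topology, ds)
    sum_s = fit_s.total
    if sum_s <= 0:
        raise ConstraintError(f"{gene or 'gene'}: sum of synonymous branch "
                              "lengths is zero; f undefined")
    f = fit_n.total / sum_s
    return ConstraintResult(gene=gene, bS=fit_s.lengths, bN=fit_n.lengths,
                            f=float(f),
                            clamped_branches=len(fit_n.clamped) + len(fit_s.clamped))


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of f between two gene groups."""

    x: list[float]
    y: list[float]
    U: float
    P: float
    method: str
    degenerate: bool = False

    @property
    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, vals in (("x", self.x), ("y", self.y)):
            arr = np.asarray(vals, dtype=float)
            out[name] = {
                "n": int(arr.size),
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
                "median": float(np.median(arr)),
            }
        return out


def mann_whitney_u(x, y, mode: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U with midranks for ties.

    ``mode``: "exact" (full enumeration of arrangements; requires no
    ties), "normal" (tie-corrected normal approximation with continuity
    correction), or "auto" (exact when n1 + n2 <= 20 and tie-free).
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ConstraintError("both groups must be nonempty")
    pooled = x + y
    has_ties = len(set(pooled)) < len(pooled)
    if len(set(pooled)) == 1:
        u = len(x) * len(y) / 2.0
        return GroupComparison(x=x, y=y, U=u, P=1.0, method="degenerate",
                               degenerate=True)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= 20 and not has_ties) else "normal"
    if mode == "exact":
        if has_ties:
            warnings.warn("ties present; falling back to normal approximation")
            mode = "normal"
    if mode == "exact":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif mode == "normal":
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=True)
    else:
        raise ConstraintError(f"unknown mode {mode!r}")
    return GroupComparison(x=x, y=y, U=float(res.statistic),
                           P=float(min(res.pvalue, 1.0)), method=mode)


def compare_types(f_values: dict[str, float], catalog: GeneCatalog,
                  mode: str = "auto") -> GroupComparison:
    """Mann-Whitney comparison of f between B- and D-type genes.

    ``f_values`` maps gene name -> f; types come from the catalog.
    Group x is B-type, group y is D-type.
    """
    types = {r.name: r.cyp_type for r in catalog}
    b = [v for g, v in f_values.items() if types.get(g) == "B"]
    d = [v for g, v in f_values.items() if types.get(g) == "D"]
    if not b or not d:
        raise ConstraintError("need at least one gene of each type")
    return mann_whitney_u(b, d, mode=mode)
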