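"""Reference-anchored classification and alignment-site discovery.

Covers: assignment of genes to B/D type by phylogenetic clustering with
labeled reference leaves, family/subfamily grouping by amino-acid
identity thresholds (single linkage at >=40% / >=55%), highly conserved
alignment columns, and group-diagnostic residues (fixed within a group
and absent outside it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import Alignment
from .distances import SiteFilterPolicy, DEFAULT_POLICY, identity_fraction
from .trees import leaf_sets


class ClassifyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# B/D type assignment

def assign_type(tree: dendropy.Tree, reference: dict[str, str],
                min_support: float = 80.0) -> dict[str, str]:
    """Assign each unlabeled leaf the type of its smallest unanimous clade.

    Walks from each query leaf rootward; the first enclosing clade that
    contains reference leaves of exactly one type *and* whose defining
    branch has bootstrap support >= ``min_support`` donates its label.
    A clade mixing reference types ends the walk: the query stays
    ``"unassigned"``.  Reference labels must include both types somewhere
    in the tree.
    """
    if not reference:
        raise ClassifyError("no labeled reference leaves")
    types = set(reference.values())
    if not types <= {"B", "D"}:
        raise ClassifyError(f"reference labels must be B/D, got {types}")
    sets = leaf_sets(tree)
    out: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label
        if name in reference:
            continue
        assigned = "unassigned"
        node = leaf.parent_node
        while node is not None:
            ref_types = {reference[x] for x in sets[node] if x in reference}
            if len(ref_types) > 1:
                break
            if len(ref_types) == 1:
                sup = None
                if node.label is not None:
                    try:
                        sup = float(node.label)
                    except ValueError:
                        sup = None
                if sup is not None and sup >= min_support:
                    assigned = next(iter(ref_types))
                    break
            node = node.parent_node
        out[name] = assigned
    return out


# ---------------------------------------------------------------------------
# identity-threshold family grouping

@dataclass
class FamilyGrouping:
    """Nested single-linkage clusters at the family/subfamily thresholds."""

    family: dict[str, int]
    subfamily: dict[str, int]


def assign_family_by_identity(aln: Alignment,
                              family_threshold: float = 0.40,
                              subfamily_threshold: float = 0.55,
                              policy: SiteFilterPolicy = DEFAULT_POLICY,
                              ) -> FamilyGrouping:
    """Group sequences by pairwise identity (single linkage).

    Sequences joined by a chain of pairs with identity >= the threshold
    share a cluster; subfamily clusters nest within family clusters
    because the subfamily threshold is the stricter one.
    """
    n = aln.n_sequences
    if n < 2:
        return FamilyGrouping({aln.ids[0]: 1} if n else {},
                              {aln.ids[0]: 1} if n else {})
    ident = np.zeros((n, n))
    for i in range(n):
        ident[i, i] = 1.0
        for j in range(i + 1, n):
            v = identity_fraction(aln, i, j, policy)
            if not np.isfinite(v):
                warnings.warn(f"undefined identity {aln.ids[i]}/{aln.ids[j]}; "
                              "treated as 0")
                v = 0.0
            ident[i, j] = ident[j, i] = v
    dist = squareform(1.0 - ident, checks=False)
    Z = linkage(dist, method="single")

    def cut(threshold):
        labels = fcluster(Z, t=1.0 - threshold + 1e-12, criterion="distance")
        return {aln.ids[i]: int(labels[i]) for i in range(n)}

    return FamilyGrouping(family=cut(family_threshold),
                          subfamily=cut(subfamily_threshold))


# ---------------------------------------------------------------------------
# conserved and diagnostic sites

@dataclass
class SiteReport:
    """Conservation summary for one alignment column (1-based original)."""

    column: int
    conservation: float
    modal_residue: str
    flagged: bool
    diagnostic_groups: dict[str, str] = field(default_factory=dict)


def conserved_sites(aln: Alignment, threshold: float = 0.95) -> list[SiteReport]:
    """Per-column conservation; columns strictly above *threshold* flagged.

    Conservation is the fraction of non-missing residues equal to the
    modal residue; all-missing columns are skipped.
    """
    if aln.n_sequences < 2:
        raise ClassifyError("need at least 2 sequences")
    missing = aln.is_missing()
    out: list[SiteReport] = []
    for c in range(aln.n_columns):
        residues = aln.matrix[~missing[:, c], c]
        if residues.size == 0:
            continue
        vals, counts = np.unique(residues, return_counts=True)
        top = int(np.argmax(counts))
        conservation = counts[top] / residues.size
        out.append(SiteReport(
            column=int(aln.column_positions[c]),
            conservation=float(conservation),
            modal_residue=str(vals[top]),
            flagged=bool(conservation > threshold),
        ))
    return out


def group_diagnostic_sites(aln: Alignment, groups: dict[str, str],
                           within_group_threshold: float = 1.0,
                           ) -> list[SiteReport]:
    """Columns where a group is fixed for a residue absent elsewhere.

    For each column and group: if at least ``within_group_threshold`` of
    the group's non-missing residues share one residue and no sequence
    outside the group carries that residue, the column is diagnostic for
    the group.  Missing data is ignored on both sides.
    """
    labels = set(groups.values())
    if len(labels) < 2:
        raise ClassifyError("need at least 2 groups")
    members = {g: [i for i, s in enumerate(aln.ids) if groups.get(s) == g]
               for g in labels}
    if any(not v for v in members.values()):
        raise ClassifyError("empty group")
    missing = aln.is_missing()
    out: list[SiteReport] = []
    for c in range(aln.n_columns):
        diag: dict[str, str] = {}
        for g, idx in members.items():
            rows = [i for i in idx if not missing[i, c]]
            if not rows:
                continue
            residues = aln.matrix[rows, c]
            vals, counts = np.unique(residues, return_counts=True)
            top = int(np.argmax(counts))
            if counts[top] / residues.size < within_group_threshold:
                continue
            residue = str(vals[top])
            outside = [i for i in range(aln.n_sequences)
                       if i not in idx and not missing[i, c]]
            if any(aln.matrix[i, c] == residue for i in outside):
                continue
            diag[g] = residue
        if diag:
            rows = ~missing[:, c]
            residues = aln.matrix[rows, c]
            vals, counts = np.unique(residues, return_counts=True)
            top = int(np.argmax(counts))
            out.append(SiteReport(
                column=int(aln.column_positions[c]),
                conservation=float(counts[top] / residues.size),
                modal_residue=str(vals[top]),
                flagged=False,
                diagnostic_groups=diag,
            ))
    return out
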