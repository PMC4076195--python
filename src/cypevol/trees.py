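"""Distance-tree construction and branch-length fitting.

Neighbor-joining (Saitou & Nei agglomeration with the Q criterion),
nonparametric bootstrap support over alignment columns, ordinary
least-squares branch lengths on a fixed topology (each pairwise distance
modeled as the sum of branch lengths on the connecting path), outgroup
rooting, and clade queries.  Trees are :class:`dendropy.Tree` objects;
bootstrap support is stored as internal-node labels (percentages).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np

from .alignment import Alignment, CodonAlignment
from .distances import DistanceMatrix


class TreeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# clade / bipartition helpers

def leaf_sets(tree: dendropy.Tree) -> dict[dendropy.Node, frozenset[str]]:
    """Map each node to the set of leaf labels below it."""
    out: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            out[node] = frozenset([node.taxon.label])
        else:
            s: frozenset[str] = frozenset()
            for ch in node.child_nodes():
                s |= out[ch]
            out[node] = s
    return out


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions as canonical leaf sets.

    Each internal branch is represented by the side *not* containing the
    alphabetically first leaf, making the encoding rooting-invariant.
    """
    sets = leaf_sets(tree)
    all_leaves = sets[tree.seed_node]
    ref = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node, s in sets.items():
        if node is tree.seed_node:
            continue
        side = all_leaves - s if ref in s else s
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def is_monophyletic(tree: dendropy.Tree,
                    leaves: set[str]) -> tuple[bool, float | None]:
    """Whether *leaves* is exactly subtended by some branch.

    Returns (flag, support-of-defining-branch) where support is the
    internal-node label parsed as a float when present.
    """
    sets = leaf_sets(tree)
    all_leaves = sets[tree.seed_node]
    want = frozenset(leaves)
    unknown = want - all_leaves
    if unknown:
        raise TreeError(f"unknown leaves {sorted(unknown)}")
    if len(want) <= 1 or want == all_leaves:
        return True, None
    for node, s in sets.items():
        if s == want:
            sup = None
            if node.label is not None:
                try:
                    sup = float(node.label)
                except ValueError:
                    sup = None
            return True, sup
    return False, None


# ---------------------------------------------------------------------------
# neighbor joining

def nj_build(D: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree (unrooted; trifurcation at the seed node).

    Ties in the Q criterion are broken towards the lexicographically
    smallest (sorted) label pair, making the result deterministic and
    independent of input label order.  For an additive input matrix the
    realized leaf-to-leaf path lengths reproduce the input exactly.
    """
    if D.n < 3:
        raise TreeError("need at least 3 taxa")
    if not D.is_finite():
        raise TreeError("non-finite distances")

    tns = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes: list[dendropy.Node] = []
    names: list[str] = []
    for lab in D.labels:
        node = dendropy.Node(taxon=tns.get_taxon(lab))
        nodes.append(node)
        names.append(lab)
    d = D.values.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if q[i, j] <= qmin + 1e-12 * max(1.0, abs(qmin)):
                    key = tuple(sorted((names[i], names[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = li
        parent.add_child(nodes[j])
        nodes[j].edge.length = lj
        dnew = 0.5 * (d[i] + d[j] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = dnew[keep]
        d = d2
        nodes = [nodes[k] for k in keep] + [parent]
        names = [names[k] for k in keep] + [min(names[i], names[j])]

    # final three-way join (three-point formulas)
    root = dendropy.Node()
    (a, b, c) = (0, 1, 2)
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    for k, ln in zip((a, b, c), (la, lb, lc)):
        root.add_child(nodes[k])
        nodes[k].edge.length = max(ln, 0.0)
    tree.seed_node = root
    tree.update_taxon_namespace()
    return tree


def path_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix realized by the tree."""
    pdm = tree.phylogenetic_distance_matrix()
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(labels)
    vals = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            v = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            vals[i, j] = vals[j, i] = v
    return DistanceMatrix(labels=labels, values=vals, method="path")


# ---------------------------------------------------------------------------
# OLS branch lengths on a fixed topology

@dataclass
class OLSFit:
    """Least-squares branch lengths keyed by branch bipartition."""

    lengths: dict[frozenset[str], float]
    sse: float
    clamped: list[frozenset[str]]

    @property
    def total(self) -> float:
        return float(sum(self.lengths.values()))


def _branch_system(tree: dendropy.Tree, labels: list[str]):
    """Path-incidence matrix over unrooted branches (merged root edges)."""
    sets = leaf_sets(tree)
    all_leaves = sets[tree.seed_node]
    if set(labels) != set(all_leaves):
        raise TreeError("distance labels do not match tree leaves")
    ref = min(all_leaves)
    branch_keys: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for node, s in sets.items():
        if node is tree.seed_node:
            continue
        side = all_leaves - s if ref in s else s
        if len(side) == 0 or len(side) == len(all_leaves):
            continue
        if side not in seen:
            seen.add(side)
            branch_keys.append(side)
    idx = {lab: k for k, lab in enumerate(labels)}
    pairs = [(i, j) for i in range(len(labels)) for j in range(i + 1, len(labels))]
    A = np.zeros((len(pairs), len(branch_keys)))
    for col, side in enumerate(branch_keys):
        for row, (i, j) in enumerate(pairs):
            ina = labels[i] in side
            inb = labels[j] in side
            if ina != inb:
                A[row, col] = 1.0
    return A, branch_keys, pairs


def ols_branch_lengths(tree: dendropy.Tree, D: DistanceMatrix) -> OLSFit:
    """Ordinary least-squares branch lengths for a fixed topology.

    Solves min ||A b - d||^2 where each pairwise distance is the sum of
    branch lengths on its connecting path.  Negative solutions are
    clamped to zero and the remaining branches refit once.
    """
    A, keys, pairs = _branch_system(tree, D.labels)
    d = np.array([D.values[i, j] for i, j in pairs])
    if not np.isfinite(d).all():
        raise TreeError("non-finite distances in OLS fit")
    b, *_ = np.linalg.lstsq(A, d, rcond=None)
    clamped = [keys[k] for k in np.where(b < -1e-12)[0]]
    if clamped:
        free = b >= -1e-12
        b2 = np.zeros_like(b)
        sol, *_ = np.linalg.lstsq(A[:, free], d, rcond=None)
        b2[free] = np.maximum(sol, 0.0)
        b = b2
    b = np.maximum(b, 0.0)
    sse = float(((A @ b - d) ** 2).sum())
    return OLSFit(lengths={k: float(v) for k, v in zip(keys, b)},
                  sse=sse, clamped=clamped)


# ---------------------------------------------------------------------------
# bootstrap

def bootstrap_support(aln: Alignment, build_fn, n_reps: int,
                      seed: int) -> dendropy.Tree:
    """Column-bootstrap support on the tree built from the full alignment.

    ``build_fn(alignment) -> dendropy.Tree`` encapsulates the distance
    method and NJ.  Codon alignments are resampled by codon, others by
    column.  Replicates whose distances are undefined are dropped with a
    warning and the support denominator adjusted.  Support percentages
    are written as internal-node labels of the returned tree.
    """
    if n_reps < 1:
        raise TreeError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    tree = build_fn(aln)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    block = 3 if isinstance(aln, CodonAlignment) else 1
    n_units = aln.n_columns // block
    used = 0
    for _ in range(n_reps):
        pick = rng.integers(0, n_units, size=n_units)
        if block == 1:
            cols = pick
        else:
            cols = (pick[:, None] * 3 + np.arange(3)[None, :]).ravel()
        rep = type(aln)(ids=list(aln.ids), matrix=aln.matrix[:, cols])
        try:
            rep_tree = build_fn(rep)
        except (TreeError, ValueError) as exc:
            warnings.warn(f"bootstrap replicate dropped: {exc}")
            continue
        used += 1
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    if used == 0:
        raise TreeError("all bootstrap replicates failed")
    sets = leaf_sets(tree)
    all_leaves = sets[tree.seed_node]
    ref = min(all_leaves)
    for node, s in sets.items():
        if node.is_leaf() or node is tree.seed_node:
            continue
        side = all_leaves - s if ref in s else s
        if side in counts:
            node.label = f"{100.0 * counts[side] / used:.10g}"
    return tree


# ---------------------------------------------------------------------------
# rooting

def root_with_outgroup(tree: dendropy.Tree,
                       outgroup: set[str] | list[str]) -> dendropy.Tree:
    """Root on the branch separating the outgroup from everything else."""
    out = frozenset(outgroup)
    t = tree.clone(depth=1)
    sets = leaf_sets(t)
    all_leaves = sets[t.seed_node]
    if not out or out == all_leaves:
        raise TreeError("outgroup must be a proper nonempty leaf subset")
    if not out <= all_leaves:
        raise TreeError(f"unknown outgroup leaves {sorted(out - all_leaves)}")
    target = None
    for node, s in sets.items():
        if node is t.seed_node:
            continue
        if s == out or s == all_leaves - out:
            target = node
            break
    if target is None:
        raise TreeError("outgroup does not form one side of any branch")
    length = target.edge.length or 0.0
    t.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0,
                     update_bipartitions=False)
    return t
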