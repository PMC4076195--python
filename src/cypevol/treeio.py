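"""Newick tree I/O and the dated species tree (chronogram).

Trees are held as :class:`dendropy.Tree` objects.  A :class:`Chronogram`
wraps an ultrametric rooted tree whose branch lengths are durations in
millions of years (myr); node ages (mya) are derived from the lengths.
Internal-node labels are used for bootstrap support elsewhere, following
the convention of writing support as a bare label after the close paren.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import dendropy

ULTRAMETRIC_TOL = 1e-6


class NewickError(ValueError):
    pass


class ChronogramError(ValueError):
    pass


def _parse_tree(source: str, is_path: bool) -> dendropy.Tree:
    kwargs = dict(
        schema="newick",
        rooting="force-rooted",
        suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    try:
        if is_path:
            return dendropy.Tree.get(path=str(source), **kwargs)
        return dendropy.Tree.get(data=source, **kwargs)
    except Exception as exc:  # dendropy raises assorted error types
        raise NewickError(f"malformed Newick: {exc}") from exc


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted tree from a Newick file."""
    return _parse_tree(path, is_path=True)


def tree_from_string(newick: str) -> dendropy.Tree:
    return _parse_tree(newick, is_path=False)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree_to_string(tree) + "\n")


def tree_to_string(tree: dendropy.Tree) -> str:
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    ).strip()


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


@dataclass
class Chronogram:
    """Ultrametric rooted species tree with node ages in mya."""

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        self._ages: dict[dendropy.Node, float] = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                self._ages[node] = 0.0
            else:
                child_ages = []
                for ch in node.child_nodes():
                    if ch.edge.length is None:
                        raise ChronogramError("chronogram branch without length")
                    if ch.edge.length < 0:
                        raise ChronogramError("negative branch duration")
                    child_ages.append(self._ages[ch] + ch.edge.length)
                ref = child_ages[0]
                for a in child_ages[1:]:
                    if abs(a - ref) > ULTRAMETRIC_TOL * max(1.0, abs(ref)):
                        raise ChronogramError(
                            f"non-ultrametric: child depths {child_ages} disagree"
                        )
                self._ages[node] = ref

    @property
    def species(self) -> list[str]:
        return leaf_labels(self.tree)

    @property
    def root_age(self) -> float:
        return self._ages[self.tree.seed_node]

    def node_age(self, node: dendropy.Node) -> float:
        return self._ages[node]

    def branch_duration(self, node: dendropy.Node) -> float:
        """Duration (myr) of the branch subtending *node*."""
        if node.parent_node is None:
            return 0.0
        return self._ages[node.parent_node] - self._ages[node]

    def mrca(self, species: set[str] | list[str]) -> dendropy.Node:
        taxa = [self.tree.taxon_namespace.get_taxon(s) for s in species]
        if any(t is None for t in taxa):
            missing = [s for s, t in zip(species, taxa) if t is None]
            raise ChronogramError(f"unknown species {missing}")
        return self.tree.mrca(taxa=taxa)

    def branch_by_clade(self, leafset: frozenset[str] | set[str]) -> dendropy.Node:
        """Node whose subtended leaf set equals *leafset* (names its branch)."""
        want = frozenset(leafset)
        for node in self.tree.preorder_node_iter():
            leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
            if leaves == want:
                return node
        raise ChronogramError(f"no branch with clade {sorted(want)}")


def read_chronogram(path: str | Path) -> Chronogram:
    return Chronogram(read_newick(path))


def chronogram_from_string(newick: str) -> Chronogram:
    return Chronogram(tree_from_string(newick))


def total_branch_length(chronogram: Chronogram) -> float:
    """Sum of branch durations (myr) over all branches of the tree."""
    total = 0.0
    for node in chronogram.tree.preorder_node_iter():
        total += chronogram.branch_duration(node)
    return total


def load_vertebrate_chronogram() -> Chronogram:
    """The packaged 15-species vertebrate chronogram.

    Node ages are TimeTree-style approximations with the human–zebrafish
    root at 400 mya; ages were chosen so the total branch length is
    exactly 2,685 myr.
    """
    ref = importlib.resources.files("cypevol.data") / "vertebrate_chronogram.nwk"
    with importlib.resources.as_file(ref) as p:
        return read_chronogram(p)
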