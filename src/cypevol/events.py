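"""Parsimonious reconstruction of gene gains, losses, and
pseudogenizations on a dated species tree, and event-rate estimation.

Each ortholog group's presence/absence (or copy-number) profile over the
chronogram's species is explained under Dollo parsimony: the group
arises exactly once, on the branch above the MRCA of the possessing
species, and copy-number changes are unit gain/loss steps placed as
late (tipward) as overall parsimony allows.  Rates are expressed as
events per 100 myr of total branch time.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

from .treeio import Chronogram

EVENT_TYPES = ("gain", "loss", "pseudogenization")


class EventError(ValueError):
    pass


@dataclass(frozen=True)
class Event:
    """One evolutionary event on a chronogram branch.

    The branch is named by the leaf set of its child clade; the root is
    the full leaf set (events at the root predate the sampled species).
    """

    branch: frozenset[str]
    type: str
    group: str

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise EventError(f"unknown event type {self.type!r}")


@dataclass
class EventSet:
    events: list[Event] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def extend(self, other: "EventSet") -> None:
        self.events.extend(other.events)

    def to_frame(self) -> pd.DataFrame:
        """Tabular form: branch ('+'-joined child clade), type, group."""
        rows = [{"branch": "+".join(sorted(ev.branch)), "type": ev.type,
                 "group": ev.group} for ev in self.events]
        return pd.DataFrame(rows, columns=["branch", "type", "group"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventSet":
        events = [Event(branch=frozenset(str(r["branch"]).split("+")),
                        type=str(r["type"]), group=str(r["group"]))
                  for _, r in df.iterrows()]
        return cls(events=events)


def count_events(events: EventSet, type: str | None = None,
                 clade: set[str] | None = None) -> int:
    """Number of events matching an optional type and clade filter.

    With ``clade`` given, only events on branches whose child clade is a
    subset of it are counted.
    """
    if type is not None and type not in EVENT_TYPES:
        raise EventError(f"unknown event type {type!r}")
    n = 0
    for ev in events:
        if type is not None and ev.type != type:
            continue
        if clade is not None and not ev.branch <= set(clade):
            continue
        n += 1
    return n


def event_rate(count: int, window_myr: float) -> float:
    """Events per 100 myr."""
    if window_myr <= 0:
        raise EventError("window must be positive")
    return 100.0 * count / window_myr


@dataclass
class EventRates:
    """Per-100-myr rates for a window of total branch time."""

    gains: int
    losses: int
    pseudogenizations: int
    window_myr: float

    @property
    def gain_rate(self) -> float:
        return event_rate(self.gains, self.window_myr)

    @property
    def loss_rate(self) -> float:
        return event_rate(self.losses, self.window_myr)

    @property
    def pseudo_rate(self) -> float:
        return event_rate(self.pseudogenizations, self.window_myr)


def rates_from_events(events: EventSet, window_myr: float) -> EventRates:
    return EventRates(
        gains=count_events(events, "gain"),
        losses=count_events(events, "loss"),
        pseudogenizations=count_events(events, "pseudogenization"),
        window_myr=window_myr,
    )


# ---------------------------------------------------------------------------
# presence/absence matrix

@dataclass
class PresenceAbsenceMatrix:
    """Ortholog-group x species integer gene counts."""

    counts: pd.DataFrame   # rows: groups, columns: species

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise EventError("negative gene counts")

    @property
    def groups(self) -> list[str]:
        return list(self.counts.index)

    @property
    def species(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="group")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path, sep="\t", comment="#", index_col="group")
        return cls(counts=df.astype(int))


# ---------------------------------------------------------------------------
# Dollo reconstruction with copy-number steps

def _interval_dist(x: int, iv: tuple[int, int]) -> int:
    lo, hi = iv
    return lo - x if x < lo else (x - hi if x > hi else 0)


def _argmin_interval(intervals: list[tuple[int, int]]) -> tuple[int, int]:
    """Minimizer interval of x -> sum of distances to the given intervals.

    Each term is the exact slope-clamped message from a child subtree in
    the L1 (unit count-step) parsimony recursion, so the sum's minimizer
    is the node's own optimal-value interval.
    """
    lo = min(iv[0] for iv in intervals)
    hi = max(iv[1] for iv in intervals)
    costs = {x: sum(_interval_dist(x, iv) for iv in intervals)
             for x in range(lo, hi + 1)}
    best = min(costs.values())
    opt = [x for x, c in costs.items() if c == best]
    return min(opt), max(opt)


def _closest(value: int, lo: int, hi: int) -> int:
    return min(max(value, lo), hi)


def dollo_reconstruct(matrix: PresenceAbsenceMatrix, tree: Chronogram,
                      ) -> tuple[pd.DataFrame, EventSet]:
    """Ancestral gene counts and minimal event set under Dollo parsimony.

    Per group: one gain at the MRCA of possessing species; within that
    subtree, ancestral integer counts minimize the total number of unit
    count-change steps (ties resolved toward counts close to the parent,
    i.e. changes placed tipward).  Returns (ancestral-count table over
    internal nodes keyed by clade leaf set, EventSet).
    """
    species = set(tree.species)
    if not set(matrix.species) <= species:
        raise EventError("matrix species not in chronogram")
    events = EventSet()
    leafsets: dict = {}
    for node in tree.tree.preorder_node_iter():
        leafsets[node] = frozenset(lf.taxon.label for lf in node.leaf_iter())
    internal = [n for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    anc_rows = {}
    for group in matrix.groups:
        row = matrix.counts.loc[group]
        possessing = {sp for sp in matrix.species if row[sp] > 0}
        if not possessing:
            warnings.warn(f"group {group}: absent from all species; skipped")
            continue
        mrca = tree.mrca(possessing) if len(possessing) > 1 else \
            next(lf for lf in tree.tree.leaf_node_iter()
                 if lf.taxon.label in possessing)
        events.events.append(Event(branch=leafsets[mrca], type="gain",
                                   group=group))
        # L1 (unit-step) ancestral counts within the MRCA subtree; a
        # virtual value of 1 at the MRCA encodes the single-copy origin.
        intervals: dict = {}
        for node in mrca.postorder_iter():
            if node.is_leaf():
                c = int(row.get(node.taxon.label, 0))
                intervals[node] = (c, c)
            else:
                intervals[node] = _argmin_interval(
                    [intervals[ch] for ch in node.child_nodes()])
        assigned: dict = {}
        if mrca.is_leaf():
            lo, hi = intervals[mrca]
        else:
            # minimize |x-1| plus the children's subtree messages directly
            lo, hi = _argmin_interval(
                [(1, 1)] + [intervals[ch] for ch in mrca.child_nodes()])
        assigned[mrca] = _closest(1, lo, hi)
        for node in mrca.preorder_iter():
            if node is mrca:
                parent_count = 1  # virtual origin copy
            else:
                parent_count = assigned[node.parent_node]
                lo, hi = intervals[node]
                # ties toward the parent's value push changes tipward
                assigned[node] = _closest(parent_count, lo, hi)
            delta = assigned[node] - parent_count
            etype = "gain" if delta > 0 else "loss"
            for _ in range(abs(delta)):
                events.events.append(Event(branch=leafsets[node],
                                           type=etype, group=group))
        anc = {}
        for node in internal:
            key = "+".join(sorted(leafsets[node]))
            anc[key] = assigned.get(node, 0)
        anc_rows[group] = anc
    node_keys = ["+".join(sorted(leafsets[n])) for n in internal]
    table = pd.DataFrame.from_dict(anc_rows, orient="index",
                                   columns=node_keys).fillna(0).astype(int)
    return table, events


def brute_force_min_events(row: dict[str, int], tree: Chronogram) -> int:
    """Exhaustive minimal event count under the single-gain constraint.

    Test oracle: enumerates all 0/1 presence assignments to internal
    nodes, requires exactly one 0->1 transition (including a virtual
    absent state above the root), and counts transitions plus unit
    copy-number steps at possessing leaves.  Refuses >8 species.
    """
    species = tree.species
    if len(species) > 8:
        raise EventError("brute force limited to 8 species")
    possessing = {sp for sp, c in row.items() if c > 0}
    if not possessing:
        raise EventError("group absent everywhere")
    cmax = max(row.values())
    nodes = list(tree.tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = None
    for states in product(range(cmax + 1), repeat=len(internal)):
        s = {n: st for n, st in zip(internal, states)}
        for n in nodes:
            if n.is_leaf():
                s[n] = int(row.get(n.taxon.label, 0))
        origins = 0   # 0 -> positive transitions (the virtual root parent is 0)
        steps = 0     # unit count-change events beyond the origin's first copy
        for n in nodes:
            parent_state = 0 if n.parent_node is None else s[n.parent_node]
            if parent_state == 0 and s[n] > 0:
                origins += 1
                steps += s[n] - 1   # copies beyond the first gained copy
            else:
                steps += abs(s[n] - parent_state)
        if origins != 1:
            continue
        total = origins + steps
        if best is None or total < best:
            best = total
    return best


# ---------------------------------------------------------------------------
# pseudogenization placement (annotation-driven)

def pseudogenization_events(shared_state: dict[str, list[str]],
                            tree: Chronogram) -> EventSet:
    """Place one pseudogenization per gene on the MRCA (or pendant) branch.

    ``shared_state`` maps gene -> species sharing the inactivating state;
    a single species puts the event on that species' pendant branch.
    """
    events = EventSet()
    for gene, spp in shared_state.items():
        if not spp:
            raise EventError(f"{gene}: no species given")
        if len(spp) == 1:
            branch = frozenset(spp)
        else:
            node = tree.mrca(set(spp))
            branch = frozenset(lf.taxon.label for lf in node.leaf_iter())
        events.events.append(Event(branch=branch, type="pseudogenization",
                                   group=gene))
    return events


# ---------------------------------------------------------------------------
# packaged fixture

def load_b_type_events() -> EventSet:
    """The packaged B-type event table (19 gains, 16 losses, 5 pseudogenizations)."""
    ref = importlib.resources.files("cypevol.data") / "b_type_events.tsv"
    with importlib.resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    events = EventSet()
    for _, r in df.iterrows():
        events.events.append(Event(branch=frozenset(str(r["branch"]).split("+")),
                                   type=str(r["type"]), group=str(r["group"])))
    return events
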