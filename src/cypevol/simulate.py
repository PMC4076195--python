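"""Synthetic-data generators with known truth.

Three generators cover the pipeline's input space:

* :func:`simulate_gene_content` draws gene gain / loss / pseudogenization
  events as Poisson processes along the branches of a dated species tree
  and tallies surviving copies per species, emulating multi-gene-family
  birth and death.
* :func:`simulate_codon_sequences` evolves in-frame codon sequences down
  a gene tree under a clock-like synonymous rate ``r_S`` with
  nonsynonymous changes accepted at probability ``f`` — the generative
  counterpart of the NG86 dN/dS ratio — and an optional switch to the
  neutral pseudogene regime partway down a branch.
* :func:`simulate_duplication_scenario` builds the 4-tip gene tree of a
  duplication predating a species calibration split, for branch-ratio
  dating recovery.

Every generator consumes one integer seed, expanded into independent
per-stream generators through :func:`stream` (a spawn-key scheme), so
adding a stage never shifts another stage's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from ._kernel import evolve_branch, random_sense_sequence
from .alignment import CodonAlignment
from .events import Event, EventSet, PresenceAbsenceMatrix
from .ng86 import index_codon
from .treeio import Chronogram

MAX_LINEAGES = 10_000


class SimulationError(ValueError):
    pass


def stream(seed: int, *key: int) -> np.random.Generator:
    """Independent generator for stream *key* derived from one seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generators.

    Rates are per 100 myr per gene lineage; ``r_S`` is synonymous
    substitutions per synonymous site per myr; ``f_functional`` is the
    acceptance probability of nonsynonymous changes while a gene works.
    """

    seed: int = 0
    gain_rate: float = 0.7
    loss_rate: float = 0.6
    pseudo_rate: float = 0.19
    r_S: float = 1e-3
    f_functional: float = 0.25
    n_codons: int = 500
    kappa: float = 1.0
    n_root_genes: int = 1


@dataclass
class SimulationTruth:
    """Ground truth emitted alongside simulated data."""

    events: EventSet = field(default_factory=EventSet)
    pseudogenization_times: dict[str, float] = field(default_factory=dict)
    branch_f: dict[str, float] = field(default_factory=dict)
    notes: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# gene-content birth-death

def simulate_gene_content(config: SimulationConfig, tree: Chronogram,
                          ) -> tuple[PresenceAbsenceMatrix, SimulationTruth]:
    """Poisson gain/loss/pseudogenization along chronogram branches.

    Each root gene founds an ortholog group; gains spawn additional
    copies of the group, losses remove a copy, pseudogenization converts
    a copy to a dead one (no further events).  Extant functional copies
    are tallied per species.
    """
    total_rate = (config.gain_rate + config.loss_rate
                  + config.pseudo_rate) / 100.0
    rng = stream(config.seed, 1)
    truth = SimulationTruth()
    species = tree.species
    leafsets = {}
    for node in tree.tree.preorder_node_iter():
        leafsets[node] = frozenset(lf.taxon.label for lf in node.leaf_iter())
    counts = {g: dict.fromkeys(species, 0)
              for g in range(config.n_root_genes)}

    def walk(node, group, n_copies_alive):
        """Evolve one group's copies down the branch above *node*."""
        if n_copies_alive == 0:
            return
        duration = tree.branch_duration(node)
        # simulate each copy independently on this branch
        copies = n_copies_alive
        t = 0.0
        # event queue per branch over all copies (rates are per lineage)
        while copies > 0:
            rate = copies * total_rate
            if rate <= 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            u = rng.random() * (config.gain_rate + config.loss_rate
                                + config.pseudo_rate)
            if u < config.gain_rate:
                copies += 1
                truth.events.events.append(
                    Event(branch=leafsets[node], type="gain", group=str(group)))
                if copies > MAX_LINEAGES:
                    raise SimulationError("lineage explosion (>10,000 copies)")
            elif u < config.gain_rate + config.loss_rate:
                copies -= 1
                truth.events.events.append(
                    Event(branch=leafsets[node], type="loss", group=str(group)))
            else:
                copies -= 1
                truth.events.events.append(
                    Event(branch=leafsets[node], type="pseudogenization",
                          group=str(group)))
        if node.is_leaf():
            counts[group][node.taxon.label] = copies
        else:
            for ch in node.child_nodes():
                walk(ch, group, copies)

    root = tree.tree.seed_node
    for g in range(config.n_root_genes):
        if root.num_child_nodes() == 0:
            counts[g][root.taxon.label] = 1
        else:
            for ch in root.child_nodes():
                walk(ch, g, 1)
    df = pd.DataFrame.from_dict(
        {str(g): counts[g] for g in counts}, orient="index",
        columns=species).fillna(0).astype(int)
    return PresenceAbsenceMatrix(counts=df), truth


# ---------------------------------------------------------------------------
# codon sequence evolution

@dataclass(frozen=True)
class RegimeSegment:
    """A stretch of branch time with one selective regime."""

    duration: float
    f: float
    pseudo: bool = False


def simulate_codon_sequences(tree: dendropy.Tree, config: SimulationConfig,
                             regimes: dict[str, list[RegimeSegment]] | None = None,
                             ) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve codon sequences down *tree* (edge lengths in myr).

    ``regimes`` optionally overrides the selective regime on the branch
    above the node with the given label (leaf label or internal node
    label); the default regime is functional evolution at
    ``config.f_functional``.  Stop codons never arise in functional
    regimes; the root sequence is uniform over sense codons.
    """
    regimes = regimes or {}
    rng_root = stream(config.seed, 2)
    rng_branch = stream(config.seed, 3)
    root_seq = random_sense_sequence(config.n_codons, rng_root)
    truth = SimulationTruth()
    seqs: dict[str, np.ndarray] = {}

    def node_key(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def walk(node, seq):
        seq = seq.copy()
        dur = node.edge.length
        if dur is None:
            dur = 0.0
        if dur < 0:
            raise SimulationError("negative branch duration")
        key = node_key(node)
        segments = regimes.get(key) if key is not None else None
        if segments is None:
            segments = [RegimeSegment(duration=dur, f=config.f_functional)]
        total = sum(s.duration for s in segments)
        if abs(total - dur) > 1e-9 * max(1.0, dur):
            raise SimulationError(
                f"regime segments on {key!r} sum to {total}, branch is {dur}")
        for seg in segments:
            if not 0.0 <= seg.f <= 1.0:
                raise SimulationError("f outside [0, 1]")
            evolve_branch(seq, seg.duration, config.r_S, seg.f,
                          seg.pseudo, rng_branch)
            if key is not None:
                truth.branch_f[key] = seg.f
        if node.is_leaf():
            seqs[node.taxon.label] = seq
        else:
            for ch in node.child_nodes():
                walk(ch, seq)

    root = tree.seed_node
    if root.is_leaf():
        seqs[root.taxon.label] = root_seq
    else:
        for ch in root.child_nodes():
            walk(ch, root_seq)
    ids = sorted(seqs)
    matrix = np.array([list("".join(index_codon(c) for c in seqs[i]))
                       for i in ids])
    return CodonAlignment(ids=ids, matrix=matrix), truth


def two_lineage_pair(config: SimulationConfig, T: float,
                     pseudo_time: float | None = None,
                     ) -> tuple[CodonAlignment, SimulationTruth]:
    """Functional/pseudogene pair diverged T myr ago.

    The lineage ``psi`` evolves functionally for ``T - pseudo_time`` myr
    and then neutrally (pseudogene regime) for ``pseudo_time`` myr; the
    ``func`` lineage stays functional.  ``pseudo_time=None`` keeps both
    functional.
    """
    tree = dendropy.Tree.get(data=f"(func:{T},psi:{T});", schema="newick",
                             preserve_underscores=True)
    regimes = None
    if pseudo_time is not None:
        if not 0.0 <= pseudo_time <= T:
            raise SimulationError("pseudogenization time outside [0, T]")
        regimes = {"psi": [
            RegimeSegment(duration=T - pseudo_time, f=config.f_functional),
            RegimeSegment(duration=pseudo_time, f=1.0, pseudo=True),
        ]}
    aln, truth = simulate_codon_sequences(tree, config, regimes)
    if pseudo_time is not None:
        truth.pseudogenization_times["psi"] = pseudo_time
    truth.notes["T"] = T
    return aln, truth


# ---------------------------------------------------------------------------
# duplication scenario

def simulate_duplication_scenario(config: SimulationConfig, T_dup: float,
                                  T_cal: float,
                                  ) -> tuple[CodonAlignment, dendropy.Tree,
                                             SimulationTruth]:
    """Gene tree of a duplication at T_dup with species splits at T_cal.

    Two paralog subtrees (``P1``, ``P2``), each splitting into two
    species tips (``a``, ``b``) at the calibration time: the expected
    substitutions-per-site ratio b_pre/b_post is (T_dup - T_cal)/T_cal
    under the clock.
    """
    if T_dup <= T_cal:
        raise SimulationError("duplication must predate the calibration split")
    pre = T_dup - T_cal
    newick = (f"((P1_a:{T_cal},P1_b:{T_cal}):{pre},"
              f"(P2_a:{T_cal},P2_b:{T_cal}):{pre});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             rooting="force-rooted",
                             preserve_underscores=True)
    aln, truth = simulate_codon_sequences(tree, config)
    truth.notes["T_dup"] = T_dup
    truth.notes["T_cal"] = T_cal
    truth.notes["expected_bpre_over_bpost"] = pre / T_cal
    return aln, tree, truth
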