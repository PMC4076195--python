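"""Seeded end-to-end validation experiments.

Each experiment simulates data with known truth through the package's
own generators and pushes it through the estimation pipeline, returning
summary statistics.  They are used both by the test suite and by
``scripts/acceptance.py``; the study conditions (rates, sequence
lengths, divergence times) are fixed here so the two always agree.

Mutation rates are chosen to keep pairwise divergences inside the
distance estimators' working regime (see docs/methods.md): deep paths
near the Jukes-Cantor saturation point acquire a convexity bias that is
a property of the estimator, not of the implementation under test.
"""

from __future__ import annotations

from dataclasses import replace

import dendropy
import numpy as np

from .constraint import estimate_f
from .dating import duplication_time, pair_ratio, pseudogenization_time
from .distances import distance_matrix
from .simulate import SimulationConfig, simulate_codon_sequences, \
    simulate_duplication_scenario, two_lineage_pair
from .treeio import Chronogram, chronogram_from_string
from .trees import bipartitions, nj_build, ols_branch_lengths, path_distances

#: clock-like 4-taxon tree (myr) used for constraint estimation
QUARTET_NEWICK = "(((A:6,B:6):23,C:29):14,D:43);"


def derive_seed(base_seed: int, tag: int, rep: int) -> int:
    """Deterministic per-replicate seed from one base seed."""
    ss = np.random.SeedSequence(base_seed, spawn_key=(tag, rep))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _quartet() -> dendropy.Tree:
    return dendropy.Tree.get(data=QUARTET_NEWICK, schema="newick",
                             preserve_underscores=True,
                             rooting="force-rooted")


def estimate_f_for_simulated_gene(seed: int, f_true: float,
                                  n_codons: int = 2000,
                                  r_S: float = 2.5e-3) -> float:
    """Simulate one 4-taxon gene at constraint f_true and re-estimate f."""
    cfg = SimulationConfig(seed=seed, r_S=r_S, f_functional=f_true,
                           n_codons=n_codons)
    aln, _ = simulate_codon_sequences(_quartet(), cfg)
    return estimate_f(aln, _quartet()).f


def f_recovery_experiment(base_seed: int, n_reps: int = 100,
                          f_true: float = 0.25,
                          n_codons: int = 2000) -> dict:
    """Median recovered f over replicates (target: within 0.05 of truth)."""
    values = [estimate_f_for_simulated_gene(derive_seed(base_seed, 1, r),
                                            f_true, n_codons)
              for r in range(n_reps)]
    return {"f_true": f_true, "n_reps": n_reps,
            "median_f": float(np.median(values)),
            "mean_f": float(np.mean(values)),
            "sd_f": float(np.std(values, ddof=1))}


def pseudo_time_recovery_experiment(base_seed: int, n_reps: int = 200,
                                    t_true: float = 6.0, T: float = 10.0,
                                    f: float = 0.25, n_codons: int = 3000,
                                    r_S: float = 5e-3) -> dict:
    """Mean recovered pseudogenization time (target: within 1 myr)."""
    values = []
    for r in range(n_reps):
        cfg = SimulationConfig(seed=derive_seed(base_seed, 2, r), r_S=r_S,
                               f_functional=f, n_codons=n_codons)
        aln, _ = two_lineage_pair(cfg, T=T, pseudo_time=t_true)
        R = pair_ratio(aln.row(0), aln.row(1))
        values.append(pseudogenization_time(R, f=f, T=T).t)
    return {"t_true": t_true, "T": T, "n_reps": n_reps,
            "mean_t": float(np.mean(values)),
            "median_t": float(np.median(values)),
            "sd_t": float(np.std(values, ddof=1))}


def date_simulated_duplication(seed: int, T_dup: float = 650.0,
                               T_cal: float = 400.0,
                               n_codons: int = 4000,
                               r_S: float = 2.5e-4) -> float:
    """One duplication-scenario replicate -> median lineage estimate (mya).

    dS distances are fitted by OLS on the true 4-tip topology; the
    internal branch is split evenly between the two paralog subtrees
    (clock assumption) to obtain b_pre per lineage.
    """
    cfg = SimulationConfig(seed=seed, r_S=r_S, n_codons=n_codons)
    aln, tree, _ = simulate_duplication_scenario(cfg, T_dup=T_dup, T_cal=T_cal)
    D = distance_matrix(aln, method="dS")
    fit = ols_branch_lengths(tree, D)
    labels = sorted(aln.ids)
    ref = labels[0]
    internal = fit.lengths[frozenset(l for l in labels
                                     if not l.startswith(ref.split("_")[0]))]
    lineages = {}
    for tip in labels:
        key = frozenset({tip}) if tip != ref \
            else frozenset(set(labels) - {ref})
        lineages[tip] = (internal / 2.0, fit.lengths[key])
    res = duplication_time(lineages, T_cal)
    return float(np.median(list(res.estimates.values())))


def duplication_recovery_experiment(base_seed: int, n_reps: int = 100,
                                    T_dup: float = 650.0,
                                    T_cal: float = 400.0) -> dict:
    """Median recovered duplication date (target: within 30 myr of truth)."""
    values = [date_simulated_duplication(derive_seed(base_seed, 3, r),
                                         T_dup, T_cal)
              for r in range(n_reps)]
    return {"T_dup_true": T_dup, "T_cal": T_cal, "n_reps": n_reps,
            "median_T": float(np.median(values)),
            "mean_T": float(np.mean(values)),
            "sd_T": float(np.std(values, ddof=1))}


# ---------------------------------------------------------------------------
# random tree generators (also used as test-instance generators)

def random_additive_tree(rng: np.random.Generator, n_taxa: int,
                         min_internal: float = 0.1,
                         min_pendant: float = 0.05) -> dendropy.Tree:
    """Random rooted binary tree with positive branch lengths.

    Internal branches are bounded away from zero so the additive
    distance matrix determines the topology uniquely.
    """
    labels = [f"T{i}" for i in range(n_taxa)]
    parts = [(lab, None) for lab in labels]  # (newick, is_internal)
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        (na, _), (nb, _) = parts[i], parts[j]
        la = min_pendant + rng.uniform(0.0, 1.0) if parts[i][1] is None \
            else min_internal + rng.uniform(0.0, 1.0)
        lb = min_pendant + rng.uniform(0.0, 1.0) if parts[j][1] is None \
            else min_internal + rng.uniform(0.0, 1.0)
        merged = f"({na}:{la:.6f},{nb}:{lb:.6f})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)]
        parts.append((merged, True))
    return dendropy.Tree.get(data=parts[0][0] + ";", schema="newick",
                             preserve_underscores=True,
                             rooting="force-rooted")


def random_chronogram(rng: np.random.Generator, n_taxa: int) -> Chronogram:
    """Random ultrametric tree with strictly increasing node ages."""
    labels = [f"S{i}" for i in range(n_taxa)]
    clusters = [(lab, 0.0) for lab in labels]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (na, aa), (nb, ab) = clusters[i], clusters[j]
        age = max(aa, ab) + rng.uniform(1.0, 10.0)
        merged = f"({na}:{age - aa:.6f},{nb}:{age - ab:.6f})"
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((merged, age))
    return chronogram_from_string(clusters[0][0] + ";")


def nj_recovery_experiment(base_seed: int, n_reps: int = 100,
                           n_taxa: int = 8) -> dict:
    """Fraction of additive matrices whose NJ tree matches the generator."""
    recovered = 0
    for r in range(n_reps):
        rng = np.random.default_rng(derive_seed(base_seed, 4, r))
        tree = random_additive_tree(rng, n_taxa)
        D = path_distances(tree)
        built = nj_build(D)
        if bipartitions(built) == bipartitions(tree):
            recovered += 1
    return {"n_reps": n_reps, "n_taxa": n_taxa, "recovered": recovered,
            "fraction": recovered / n_reps}


def power_experiment(base_seed: int, n_reps: int = 200,
                     f_b: float = 0.24, n_b: int = 22,
                     f_d: float = 0.33, n_d: int = 35,
                     n_codons: int = 500) -> dict:
    """Fraction of replicates with median(f_D) > median(f_B).

    Each replicate simulates full B and D gene sets at the group-level
    constraints and per-gene lengths of a typical CYP study and
    re-estimates f per gene.
    """
    wins = 0
    for r in range(n_reps):
        base = derive_seed(base_seed, 5, r)
        fb = [estimate_f_for_simulated_gene(derive_seed(base, 0, g), f_b,
                                            n_codons) for g in range(n_b)]
        fd = [estimate_f_for_simulated_gene(derive_seed(base, 1, g), f_d,
                                            n_codons) for g in range(n_d)]
        if np.median(fd) > np.median(fb):
            wins += 1
    return {"n_reps": n_reps, "f_b": f_b, "n_b": n_b, "f_d": f_d,
            "n_d": n_d, "wins": wins, "fraction": wins / n_reps}
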