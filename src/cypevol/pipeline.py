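"""File-based orchestration of the analysis stages.

Each stage reads its inputs from, and writes its outputs to, a run
directory — no state is passed in memory between stages, so any stage's
outputs can be replaced by fixtures.  Every stage writes, atomically:

* its named output files (TSV / FASTA / Newick / JSON),
* ``<stage>.log.json`` recording the package version, the configuration
  hash, the seed, and the wall-clock duration,
* ``<stage>.warnings.json`` — a machine-readable sidecar collecting
  soft problems (clamped branches, dropped replicates, undefined
  distances) encountered while running.

Missing upstream outputs raise :class:`MissingInputError` naming the
stage that should have produced them.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings as _warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .alignment import CodonAlignment, read_codon_alignment, write_alignment
from .catalog import load_human_catalog, read_catalog
from .classify import assign_type
from .constraint import ConstraintError, compare_types, estimate_f
from .dating import DatingError, duplication_time_from_tree, pair_ratio, \
    pseudogenization_time
from .distances import SiteFilterPolicy, distance_matrix, DistanceMatrix
from .events import PresenceAbsenceMatrix, dollo_reconstruct, event_rate, \
    load_b_type_events, rates_from_events
from .simulate import SimulationConfig, simulate_duplication_scenario, \
    simulate_gene_content, two_lineage_pair
from .treeio import Chronogram, load_vertebrate_chronogram, read_chronogram, \
    read_newick, total_branch_length, tree_to_string, write_newick
from .trees import nj_build

STAGES = ("simulate", "distances", "tree", "classify", "events",
          "date-duplication", "date-pseudogene", "constraint", "report")


class PipelineError(ValueError):
    """User-correctable problem: bad config or bad inputs."""


class MissingInputError(PipelineError):
    def __init__(self, path: Path, producer: str):
        super().__init__(
            f"missing input {path}; run the '{producer}' stage first "
            f"(or place the file there yourself)")
        self.path = path
        self.producer = producer


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs; JSON-serializable, hashed into the logs."""

    out_dir: str = "run"
    seed: int = 0
    # site filtering
    max_gap_fraction: float = 0.20
    deletion: str = "pairwise"
    # distances / tree
    distance_method: str = "p"
    correction: str = "jukes_cantor"
    # classification
    min_support: float = 80.0
    # calibration and windows
    T_cal: float = 400.0
    window_myr: float | None = None       # None -> chronogram total
    # dating inputs
    f_functional: float = 0.25
    pair_T: float = 10.0
    dup_clade: list[str] = field(default_factory=list)
    calibrations: dict[str, list[str]] = field(default_factory=dict)
    # simulation
    sim: str = "gene-content"             # gene-content | pair | duplication
    sim_config: dict = field(default_factory=dict)
    sim_T_dup: float = 650.0
    sim_pair_pseudo_time: float | None = 6.0
    # file overrides (defaults live inside the run directory)
    chronogram: str | None = None          # None -> packaged chronogram
    catalog: str | None = None             # None -> packaged catalog
    topology: str | None = None            # constraint-stage fixed topology
    genes_dir: str | None = None           # constraint-stage alignments

    def policy(self) -> SiteFilterPolicy:
        return SiteFilterPolicy(max_gap_fraction=self.max_gap_fraction,
                                deletion_mode=self.deletion)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """RunConfig from an optional JSON file, with keyword overrides."""
    data: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise PipelineError(f"config file not found: {p}")
        try:
            data = json.loads(p.read_text())
        except json.JSONDecodeError as exc:
            raise PipelineError(f"config file {p} is not valid JSON: {exc}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise PipelineError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# atomic writes and logging

def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)


def _write_json(path: Path, obj) -> None:
    _atomic_write(path, json.dumps(obj, indent=2, sort_keys=True) + "\n")


def _write_tsv(path: Path, df: pd.DataFrame, index: bool = False) -> None:
    _atomic_write(path, df.to_csv(sep="\t", index=index))


def _finish(out: Path, stage: str, config: RunConfig, started: float,
            outputs: list[str], warnings: list[str]) -> dict:
    log = {
        "stage": stage,
        "version": __version__,
        "config_hash": config.hash(),
        "seed": config.seed,
        "duration_s": round(time.time() - started, 3),
        "outputs": outputs,
        "n_warnings": len(warnings),
    }
    _write_json(out / f"{stage}.log.json", log)
    _write_json(out / f"{stage}.warnings.json", warnings)
    return log


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingInputError(path, producer)
    return path


def _chronogram(config: RunConfig) -> Chronogram:
    if config.chronogram is None:
        return load_vertebrate_chronogram()
    return read_chronogram(_require(Path(config.chronogram), "user input"))


def _catalog(config: RunConfig):
    if config.catalog is None:
        return load_human_catalog()
    return read_catalog(_require(Path(config.catalog), "user input"))


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    sim_cfg = SimulationConfig(seed=config.seed, **config.sim_config)
    outputs: list[str] = []
    _write_json(out / "sim_config.json",
                {"mode": config.sim, **asdict(sim_cfg)})
    outputs.append("sim_config.json")
    if config.sim == "gene-content":
        tree = _chronogram(config)
        matrix, truth = simulate_gene_content(sim_cfg, tree)
        matrix.to_tsv(out / "gene_content.tsv")
        outputs.append("gene_content.tsv")
        _write_tsv(out / "true_events.tsv", truth.events.to_frame())
        outputs.append("true_events.tsv")
    elif config.sim == "pair":
        aln, truth = two_lineage_pair(sim_cfg, T=config.pair_T,
                                      pseudo_time=config.sim_pair_pseudo_time)
        write_alignment(aln, out / "alignment.fasta")
        outputs.append("alignment.fasta")
        _write_json(out / "truth.json", {
            "T": config.pair_T,
            "pseudogenization_times": truth.pseudogenization_times,
        })
        outputs.append("truth.json")
    elif config.sim == "duplication":
        aln, tree, truth = simulate_duplication_scenario(
            sim_cfg, T_dup=config.sim_T_dup, T_cal=config.T_cal)
        write_alignment(aln, out / "alignment.fasta")
        write_newick(tree, out / "gene_tree.nwk")
        _write_json(out / "truth.json", dict(truth.notes))
        outputs += ["alignment.fasta", "gene_tree.nwk", "truth.json"]
    else:
        raise PipelineError(f"unknown simulation mode {config.sim!r}")
    return outputs


def _stage_distances(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    aln_path = _require(out / "alignment.fasta", "simulate")
    aln = read_codon_alignment(aln_path)
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        D = distance_matrix(aln, method=config.distance_method,
                            policy=config.policy(),
                            correction=config.correction)
    warn.extend(str(w.message) for w in caught)
    vals = D.values[np.triu_indices(len(D.labels), k=1)]
    if not np.all(np.isfinite(vals)):
        warn.append("distance matrix contains undefined (saturated) entries")
    D.to_tsv(out / "distances.tsv")
    return ["distances.tsv"]


def _stage_tree(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    D = DistanceMatrix.from_tsv(_require(out / "distances.tsv", "distances"))
    tree = nj_build(D)
    write_newick(tree, out / "tree.nwk")
    return ["tree.nwk"]


def _stage_classify(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    tree = read_newick(_require(out / "tree.nwk", "tree"))
    catalog = _catalog(config)
    reference = {r.name: r.cyp_type for r in catalog
                 if r.cyp_type in ("B", "D")}
    in_tree = {lf.taxon.label for lf in tree.leaf_node_iter()}
    reference = {k: v for k, v in reference.items() if k in in_tree}
    if not reference:
        raise PipelineError("no reference genes from the catalog are present "
                            "in tree.nwk; cannot assign types")
    assignments = assign_type(tree, reference, min_support=config.min_support)
    rows = [{"gene": g, "cyp_type": t or "unassigned"}
            for g, t in sorted(assignments.items())]
    _write_tsv(out / "type_assignments.tsv", pd.DataFrame(rows))
    return ["type_assignments.tsv"]


def _stage_events(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    tree = _chronogram(config)
    window = config.window_myr or total_branch_length(tree)
    content = out / "gene_content.tsv"
    if content.exists():
        matrix = PresenceAbsenceMatrix.from_tsv(content)
        ancestral, events = dollo_reconstruct(matrix, tree)
        _write_tsv(out / "ancestral_counts.tsv", ancestral, index=True)
        source = "gene_content.tsv (Dollo reconstruction)"
        extra = ["ancestral_counts.tsv"]
    else:
        events = load_b_type_events()
        source = "packaged curated event table"
        extra = []
        warn.append("no gene_content.tsv in the run directory; "
                    "using the packaged curated event table")
    _write_tsv(out / "events.tsv", events.to_frame())
    rates = rates_from_events(events, window)
    df = pd.DataFrame([
        {"event": "gain", "count": rates.gains,
         "window_myr": window, "rate_per_100myr": rates.gain_rate},
        {"event": "loss", "count": rates.losses,
         "window_myr": window, "rate_per_100myr": rates.loss_rate},
        {"event": "pseudogenization", "count": rates.pseudogenizations,
         "window_myr": window, "rate_per_100myr": rates.pseudo_rate},
    ])
    df["rate_rounded"] = df["rate_per_100myr"].round(1)
    # rates below 0.5 keep a second decimal so they stay nonzero in print
    df.loc[df["rate_per_100myr"] < 0.5, "rate_rounded"] = \
        df["rate_per_100myr"].round(2)
    _write_tsv(out / "event_rates.tsv", df)
    _write_json(out / "event_source.json", {"source": source})
    return ["events.tsv", "event_rates.tsv", "event_source.json"] + extra


def _stage_date_duplication(out: Path, config: RunConfig,
                            warn: list[str]) -> list[str]:
    aln = read_codon_alignment(_require(out / "alignment.fasta", "simulate"))
    gt_path = _require(out / "gene_tree.nwk", "simulate")
    topology = read_newick(gt_path)
    D = distance_matrix(aln, method=config.distance_method,
                        policy=config.policy(), correction=config.correction)
    from .trees import leaf_sets as _ls, ols_branch_lengths
    fit = ols_branch_lengths(topology, D)
    if fit.clamped:
        warn.append(f"{len(fit.clamped)} OLS branch lengths clamped to zero")
    # Write fitted lengths back onto the rooted topology.  OLS fits the
    # unrooted tree, so the bipartition carrying the root gets its length
    # split evenly between the two root edges (clock assumption).
    fitted = topology.clone(depth=1)
    sets = _ls(fitted)
    all_leaves = sets[fitted.seed_node]
    ref = min(all_leaves)
    root = fitted.seed_node
    for node, clade in sets.items():
        if node is root:
            continue
        side = all_leaves - clade if ref in clade else clade
        length = fit.lengths.get(side)
        if length is None:
            continue
        node.edge.length = length / 2.0 if node.parent_node is root else length
    if config.dup_clade:
        dup_clade = set(config.dup_clade)
        calibrations = {k: set(v) for k, v in config.calibrations.items()}
    else:
        # default layout from simulate_duplication_scenario: tips named
        # <paralog>_<species>; each paralog subtree is a calibration clade
        labels = sorted(aln.ids)
        dup_clade = set(labels)
        calibrations = {}
        for lab in labels:
            prefix = lab.split("_")[0]
            calibrations[lab] = {l for l in labels
                                 if l.startswith(prefix + "_")}
    result = duplication_time_from_tree(fitted, dup_clade, calibrations,
                                        config.T_cal)
    rows = [{"lineage": k, "estimate_mya": v}
            for k, v in sorted(result.estimates.items())]
    _write_tsv(out / "duplication_dates.tsv", pd.DataFrame(rows))
    _write_json(out / "duplication_summary.json", {
        "T_cal": config.T_cal,
        "youngest_mya": result.youngest,
        "oldest_mya": result.oldest,
    })
    return ["duplication_dates.tsv", "duplication_summary.json"]


def _stage_date_pseudogene(out: Path, config: RunConfig,
                           warn: list[str]) -> list[str]:
    aln = read_codon_alignment(_require(out / "alignment.fasta", "simulate"))
    if aln.n_sequences != 2:
        raise PipelineError("pseudogene dating expects a 2-sequence "
                            "(functional vs pseudogene) alignment")
    a, b = aln.row(0), aln.row(1)
    try:
        R = pair_ratio(a, b, correction=config.correction)
        dated = pseudogenization_time(R, f=config.f_functional, T=config.pair_T)
    except DatingError as exc:
        raise PipelineError(str(exc))
    if dated.clamped:
        warn.append(f"raw estimate {dated.raw_t:.3f} clamped into "
                    f"[0, {config.pair_T}]")
    _write_json(out / "pseudogene_date.json", {
        "R": dated.R, "f": dated.f, "T": dated.T,
        "t_mya": dated.t, "raw_t_mya": dated.raw_t,
        "clamped": dated.clamped,
    })
    return ["pseudogene_date.json"]


def _stage_constraint(out: Path, config: RunConfig,
                      warn: list[str]) -> list[str]:
    if config.genes_dir is None or config.topology is None:
        raise PipelineError("constraint stage needs 'genes_dir' (directory of "
                            "4-taxon codon FASTA files named <gene>.fasta) "
                            "and 'topology' (Newick) in the config")
    genes_dir = _require(Path(config.genes_dir), "user input")
    topology = read_newick(_require(Path(config.topology), "user input"))
    catalog = _catalog(config)
    rows = []
    f_values: dict[str, float] = {}
    for path in sorted(genes_dir.glob("*.fasta")):
        gene = path.stem
        aln = read_codon_alignment(path)
        try:
            res = estimate_f(aln, topology, gene=gene,
                             policy=config.policy(),
                             correction=config.correction)
        except (ConstraintError, DatingError, ValueError) as exc:
            warn.append(f"{gene}: dropped ({exc})")
            continue
        if res.clamped_branches:
            warn.append(f"{gene}: {res.clamped_branches} branch lengths "
                        "clamped to zero")
        f_values[gene] = res.f
        rows.append({"gene": gene, "sum_bS": res.sum_bS,
                     "sum_bN": res.sum_bN, "f": res.f,
                     "constraint": res.constraint})
    if not rows:
        raise PipelineError(f"no usable gene alignments in {genes_dir}")
    _write_tsv(out / "constraint.tsv", pd.DataFrame(rows))
    outputs = ["constraint.tsv"]
    try:
        cmp = compare_types(f_values, catalog)
    except ConstraintError as exc:
        warn.append(f"group comparison skipped: {exc}")
    else:
        _write_json(out / "constraint_comparison.json", {
            "U": cmp.U, "P": cmp.P, "method": cmp.method,
            "B": cmp.summary["x"], "D": cmp.summary["y"],
        })
        outputs.append("constraint_comparison.json")
    return outputs


def _stage_report(out: Path, config: RunConfig, warn: list[str]) -> list[str]:
    lines: list[str] = []
    found = False
    rates_path = out / "event_rates.tsv"
    if rates_path.exists():
        found = True
        df = pd.read_csv(rates_path, sep="\t")
        for _, row in df.iterrows():
            lines.append(f"{row['event']} rate: {row['rate_rounded']} per "
                         f"100 myr ({int(row['count'])} events / "
                         f"{row['window_myr']:g} myr) "
                         f"[event_rates.tsv]")
    ta = out / "type_assignments.tsv"
    if ta.exists():
        found = True
        df = pd.read_csv(ta, sep="\t")
        counts = df["cyp_type"].value_counts().to_dict()
        lines.append(f"type assignments: {counts} [type_assignments.tsv]")
    dup = out / "duplication_summary.json"
    if dup.exists():
        found = True
        d = json.loads(dup.read_text())
        lines.append(f"duplication date (youngest estimate): "
                     f"{d['youngest_mya']:.0f} mya "
                     f"(calibration {d['T_cal']:g} mya) "
                     f"[duplication_summary.json]")
    psi = out / "pseudogene_date.json"
    if psi.exists():
        found = True
        d = json.loads(psi.read_text())
        lines.append(f"pseudogenization date: {d['t_mya']:.1f} mya "
                     f"(R = {d['R']:.3f}, f = {d['f']:g}, "
                     f"T = {d['T']:g}) [pseudogene_date.json]")
    con = out / "constraint_comparison.json"
    if con.exists():
        found = True
        d = json.loads(con.read_text())
        lines.append(f"constraint: mean f B = {d['B']['mean']:.2f} "
                     f"(n = {d['B']['n']}), D = {d['D']['mean']:.2f} "
                     f"(n = {d['D']['n']}); Mann-Whitney P = {d['P']:.4f} "
                     f"[constraint_comparison.json]")
    if not found:
        raise PipelineError(
            "report stage found none of its inputs in "
            f"{out}; required at least one of: event_rates.tsv (events), "
            "type_assignments.tsv (classify), duplication_summary.json "
            "(date-duplication), pseudogene_date.json (date-pseudogene), "
            "constraint_comparison.json (constraint)")
    _atomic_write(out / "report.txt", "\n".join(lines) + "\n")
    return ["report.txt"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "distances": _stage_distances,
    "tree": _stage_tree,
    "classify": _stage_classify,
    "events": _stage_events,
    "date-duplication": _stage_date_duplication,
    "date-pseudogene": _stage_date_pseudogene,
    "constraint": _stage_constraint,
    "report": _stage_report,
}


def run_stage(stage: str, config: RunConfig) -> dict:
    """Run one stage; returns the log record written to disk."""
    if stage not in _STAGE_FN:
        raise PipelineError(f"unknown stage {stage!r}; "
                            f"choose from {', '.join(STAGES)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warn: list[str] = []
    started = time.time()
    outputs = _STAGE_FN[stage](out, config, warn)
    return _finish(out, stage, config, started, outputs, warn)
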