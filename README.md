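# cypevol

Comparative-evolution toolkit for the cytochrome P450 (CYP) superfamily.

CYP genes split into two ecological classes: **B-type** (biosynthesis:
steroid, cholesterol and vitamin metabolism) and **D-type**
(detoxification: xenobiotic metabolism). The two classes evolve very
differently — B-type repertoires are stable across vertebrates while
D-type repertoires churn through frequent duplication, loss and
pseudogenization. `cypevol` implements the full analysis chain needed to
quantify that contrast:

* **Gene catalogs** — typed records (family/subfamily/clan, B/D type,
  functional/pseudogene, genomic cluster, parent gene of a pseudogene)
  with a packaged human CYP catalog (57 functional genes: 35 D-type,
  22 B-type; 17 pseudogenes with identified parent genes).
* **Distances** — p-distance, maximum-likelihood JTT protein distance,
  and Nei–Gojobori (1986) dS/dN with Jukes–Cantor correction, behind a
  shared gap-filtering policy (columns with >20 % gaps removed;
  pairwise or complete deletion).
* **Trees** — Saitou–Nei neighbor joining with deterministic
  tie-breaking, codon-block bootstrap support, outgroup rooting, and
  ordinary-least-squares branch lengths on a fixed topology.
* **Classification** — B/D type assignment of query genes by the
  smallest bootstrap-supported reference clade; identity-threshold
  family (≥40 %) and subfamily (≥55 %) grouping; conserved and
  group-diagnostic alignment sites.
* **Events** — Dollo parsimony reconstruction of gene gain / loss /
  pseudogenization on a dated species tree (integer copy numbers, exact
  L1 dynamic program verified against exhaustive search) and rates per
  100 million years. A packaged 15-species vertebrate chronogram (total
  branch length 2,685 myr, human–zebrafish split 400 mya) and a curated
  B-type event table (19 gains, 16 losses, 5 pseudogenizations) ship as
  fixtures.
* **Dating** — duplication ages from clock-calibrated branch-length
  ratios, and pseudogenization ages from the constrained/neutral dN/dS
  mixture t = 2T(R − f)/(1 − f).
* **Constraint** — per-gene f = ΣbN/ΣbS from independent OLS fits of
  the dN and dS matrices on a fixed 4-taxon tree, and Mann–Whitney U
  comparison (exact by default for small tie-free samples) of f between
  B- and D-type genes.
* **Synthetic data** — seeded generators with known truth for every
  estimator: birth–death gene content on a chronogram, an
  acceptance-probability codon process calibrated so the realized
  synonymous rate equals the nominal r_S, and duplication scenarios.

## Worked example

Estimate when a pseudogene died, from simulated sequence data with a
known answer (a gene pair that diverged T = 10 mya; the pseudogene
lineage lost function t = 6 mya):

```python
from cypevol import (SimulationConfig, two_lineage_pair,
                     pair_ratio, pseudogenization_time)

cfg = SimulationConfig(seed=5, r_S=5e-3, f_functional=0.25, n_codons=2000)
aln, truth = two_lineage_pair(cfg, T=10.0, pseudo_time=6.0)

R = pair_ratio(aln.sequence("func"), aln.sequence("psi"))
dated = pseudogenization_time(R, f=0.25, T=10.0)
print(f"R = {R:.3f} -> t = {dated.t:.2f} mya (truth: 6)")
```

prints

```
R = 0.497 -> t = 6.58 mya (truth: 6)
```

Single replicates are noisy; the mean over 200 replicates recovers the
truth within ±1 myr (`cypevol.validation.pseudo_time_recovery_experiment`).

The same analysis from the command line, stage by stage through a run
directory, with the study conditions in a JSON config:

```
$ cat ex.json
{"sim": "pair", "pair_T": 10.0, "sim_pair_pseudo_time": 6.0,
 "f_functional": 0.25, "seed": 5,
 "sim_config": {"r_S": 0.005, "n_codons": 2000, "f_functional": 0.25}}
$ cypevol simulate --config ex.json --out run
simulate: wrote sim_config.json, alignment.fasta, truth.json (config f777dc2e8c10c8a9, seed 5)
$ cypevol date-pseudogene --config ex.json --out run
date-pseudogene: wrote pseudogene_date.json (config f777dc2e8c10c8a9, seed 5)
$ cypevol report --config ex.json --out run && cat run/report.txt
pseudogenization date: 6.6 mya (R = 0.497, f = 0.25, T = 10) [pseudogene_date.json]
```

And the packaged fixtures reproduce the headline B-type event rates:

```
$ cypevol events --out run2 && cypevol report --out run2
$ cat run2/report.txt
gain rate: 0.7 per 100 myr (19 events / 2685 myr) [event_rates.tsv]
loss rate: 0.6 per 100 myr (16 events / 2685 myr) [event_rates.tsv]
pseudogenization rate: 0.19 per 100 myr (5 events / 2685 myr) [event_rates.tsv]
```

Every stage writes a `<stage>.log.json` (package version, config hash,
seed) and a `<stage>.warnings.json` sidecar; reruns of the same config
are byte-identical.

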