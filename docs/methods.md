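# Methods

Model definitions, parameter defaults, and the numerical choices behind
`cypevol`. Everything here is implemented in the package and exercised
by the test suite; section references name the module that owns each
piece.

## Distances (`cypevol.distances`, `cypevol.ng86`, `cypevol.jtt`)

**Gap policy.** A `SiteFilterPolicy` removes alignment columns whose
gap/ambiguity fraction strictly exceeds `max_gap_fraction`
(default 0.20) and chooses between *pairwise deletion* (each pair uses
the columns where both partners are resolved) and *complete deletion*
(only columns resolved in every sequence). For codon methods the filter
keeps or drops whole codons so frame is preserved. Missing characters:
`-`, `N` (nucleotide), `-`, `X` (protein).

**Nei–Gojobori (1986) dS/dN.** Each of a codon's nine single-nucleotide
changes carries 1/3 of a site, classified synonymous or nonsynonymous
by the standard genetic code; changes creating a stop codon are dropped
from both classes, so per-codon sites total 3 minus 1/3 per
stop-adjacent change. (Weighting positions by the count of non-stop
alternatives instead would over-weight nonsynonymous sites at
stop-adjacent positions and bias dN/dS below its generative value — the
1/3 convention is the one under which the estimator is consistent with
the acceptance-probability generator below.) Differences between codons
differing at 2–3 positions are averaged with equal weight over all
minimal substitution pathways; pathways through a stop are excluded
unless all are blocked. Codon pairs containing a stop or an unresolved
base are skipped and tallied. Proportions are corrected with
Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), undefined (∞) at p ≥ 3/4.
All per-codon quantities are precomputed into 64/64×64 lookup tables.

*Validity limits.* (i) Pathway averaging can attribute fractional
nonsynonymous differences to codons hit twice even under purely
synonymous evolution (Leu TTA vs CTC: one all-synonymous and one
nonsynonymous minimal path), so dN under complete constraint is ~0, not
exactly 0. (ii) Near saturation (path dS ≳ 1) Jukes–Cantor convexity
inflates expected distances; recovery experiments therefore run at
rates keeping the deepest pairwise dS ≲ 0.4.

**JTT protein distance.** One-parameter maximum likelihood under the
Jones–Taylor–Thornton replacement model (published rate constants,
normalized to one substitution per site); the branch length maximizes
Σ log[π_a P_ab(t)] over comparable sites via bounded scalar
optimization on t ∈ [10⁻⁹, 10]; saturated pairs return ∞.

## Trees (`cypevol.trees`)

**Neighbor joining** follows Saitou–Nei with the standard Q-criterion;
ties are broken by the lexicographically smallest sorted label pair, so
output is deterministic. The final three taxa are joined exactly.
Negative pendant edges are clamped to zero. NJ recovers the generating
topology on every additive matrix (verified 100/100 at 8 taxa, and
cross-checked against an independent implementation).

**OLS branch lengths** on a fixed topology solve min‖Ab − d‖² where A
is the path-incidence matrix over the unrooted branches (the two root
edges merge into one bipartition). Negative solutions are clamped to
zero and the remainder refit once. On additive input the fit is exact
(SSE ≈ 10⁻²⁹).

**Bootstrap** resamples columns (whole codons for codon alignments),
rebuilds with the same pipeline, and reports bipartition percentages as
internal node labels; replicates with undefined distances are dropped
and the denominator adjusted.

## Classification (`cypevol.classify`)

A query gene takes the type (B or D) of the smallest enclosing clade
that (a) contains reference genes of exactly one type and (b) is
supported at ≥ `min_support` (default 80 %). Meeting a mixed clade ends
the walk: the gene stays unassigned rather than guessing. Family and
subfamily grouping uses single-linkage clustering of pairwise identity
at the conventional 40 % / 55 % thresholds.

## Events (`cypevol.events`)

Gene content is an integer copy-number character per ortholog group.
Under Dollo parsimony each group has exactly one origin, placed on the
branch to the MRCA of possessing species; within that subtree ancestral
copy numbers minimize total unit count-changes (an exact L1
message-passing dynamic program; minimizer intervals are computed from
the children's piecewise-linear messages, and ties resolve toward the
parent's value, pushing changes tipward). Each unit increase is a gain,
each unit decrease a loss; pseudogenization events come from annotation
(shared inactivating states place one event on the MRCA branch of the
sharing species). The DP is verified against exhaustive enumeration of
all ancestral assignments on ≤6-taxon instances.

Rates are events per 100 myr: 100 × count / window, where the window is
the chronogram's total branch length (2,685 myr for the packaged
15-species vertebrate tree) or a lineage-specific path (432 myr for the
human-lineage pseudogenization window).

## Dating (`cypevol.dating`)

**Duplications.** With a clock, a duplication predating a calibrated
species split at T_cal satisfies T_dup = T_cal · (b_pre + b_post) /
b_post per tip lineage, where b_post spans calibration node → tip and
b_pre duplication node → calibration node. Lineage estimates disagree
under rate variation; the youngest is the conservative headline. When
branch lengths come from an unrooted OLS fit, the bipartition carrying
the duplication node is split evenly between the two paralog subtrees
(clock assumption).

**Pseudogenizations.** A pseudogene evolves under constraint f until it
dies at t and neutrally after; over a pair path of 2T against a
functional ortholog the observed R = dN/dS is the time-average
R = (f(2T − t) + t)/2T, inverted as **t = 2T(R − f)/(1 − f)**, clamped
into [0, T] with a flag. Uncertainty via codon-block bootstrap
percentile intervals.

## Constraint (`cypevol.constraint`)

Per gene, dN and dS distance matrices over a fixed 4-taxon tree are
independently fit by OLS; f = ΣbN/ΣbS (negative branches clamped
first), functional constraint = 1 − f. The fixed topology is
appropriate for single-copy orthologs from species whose relationships
are uncontroversial. Group comparison uses two-sided Mann–Whitney U:
exact when n1 + n2 ≤ 20 without ties (verified identical to full
enumeration for all n1 + n2 ≤ 12), otherwise tie-corrected normal
approximation with continuity correction.

## Synthetic data (`cypevol.simulate`, `cypevol._kernel`)

**Gene content.** Each copy lineage draws waiting times from the
aggregate gain+loss+pseudogenization rate (per 100 myr per lineage)
along each chronogram branch; gains add a copy of the same group,
losses remove one, pseudogenization removes it from the functional
tally. Lineage explosions abort at 10,000 copies.

**Codon sequences.** An acceptance-probability process: candidate
single-nucleotide changes arrive per site at rate r_S (each alternative
base at r_S/3); synonymous candidates are always accepted, nonsynonymous
with probability f, stop-creating candidates are rejected in functional
regimes and accepted in pseudogene regimes. With uniform alternatives
this calibrates exactly: the realized synonymous rate per NG86
synonymous site equals r_S, so branch lengths in myr convert to dS as
r_S·t (verified: regression of dS on path time gives slope r_S,
R² > 0.99). The acceptance model matches NG86's definition of f
directly, which is what makes recovery tests interpretable. Root
sequences are uniform over the 61 sense codons. The inner loop is
numba-compiled when available, with a bit-identical interpreted
fallback. One integer seed expands into independent per-stream
generators via spawn keys, so adding a stage never shifts another
stage's draws.

**Scope.** No indels, no alignment error, no transition bias by default
(κ = 1 keeps NG86 unbiased), no demographic processes.

## Validation experiments (`cypevol.validation`)

Study conditions are fixed in one module shared by the tests and
`scripts/acceptance.py`:

| experiment | conditions | result (seed 1) |
|---|---|---|
| constraint f recovery | f = 0.25, 2,000 codons, r_S = 2.5·10⁻³, 4-taxon clock tree, 100 reps | median 0.254 |
| pseudogenization time | t = 6 of T = 10, 3,000 codons, r_S = 5·10⁻³, 200 reps | mean 6.19 |
| duplication time | T_dup = 650, T_cal = 400, 4,000 codons, r_S = 2.5·10⁻⁴, 100 reps | median 653 |
| NJ topology | random additive 8-taxon matrices, 100 reps | 100/100 |
| B vs D power | B: f = 0.24, n = 22; D: f = 0.33, n = 35; 500 codons/gene, 200 reps | median(D) > median(B) in 100 % |

The duplication experiment's mutation rate is deliberately low: at
r_S = 10⁻³ the cross-paralog paths reach dS ≈ 1.3 and the
Jukes–Cantor/NG86 combination acquires a ≈ +25 myr convexity bias — a
property of the distance estimator near saturation, not of the
implementation. Problem sizes (taxon counts, codon counts, replicate
counts) are this package's validation choices.

## Fixtures (`cypevol/data/`)

* `human_cyp_catalog.tsv` — 76 human CYP records (57 functional, 17
  pseudogenes with parent genes, 2 without); genomic cluster
  memberships for the five major clusters (12, 4, 6, 6, 7 genes).
* `vertebrate_chronogram.nwk` — 15 species, integer node ages, root
  (human–zebrafish) 400 mya, total branch length exactly 2,685 myr.
* `b_type_events.tsv` — curated B-type gain/loss/pseudogenization
  events (19/16/5) on those branches; rows flagged `approx` mark
  placements interpolated from clade-level statements rather than
  per-branch listings.
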