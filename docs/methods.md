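# Methods

## Model and procedure

### Trait model (Dollo)

The mycorrhizal-competence trait is binary (host/nonhost) and assumed to
have a single origin before the root of the species panel, so ancestral
reconstruction is Dollo parsimony with the root fixed to present and no
regains. Under these constraints the minimal reconstruction is unique: one
loss on the stem branch of every maximal clade whose species are all
nonhost. `infer_trait_losses` returns exactly that set; branches are
identified by their descendant species set, which is stable across
serialisation. Species with unknown presence state never count for or
against any quantity (genome completeness varies across public
assemblies, and a gene can be known only from transcriptome evidence).

### Coelimination score and permutation null

For a family's presence row, `host_retention_fraction` is the fraction of
trait-positive species (with known state) retaining the gene, and
`n_independent_colosses` counts trait-loss events whose known descendant
species all lack the gene (events with only unknown descendants are not
counted). The family is flagged coeliminated when
`n_independent_colosses >= k_min` (default 3) and retention `>=
host_retention_min` (default 0.75). Both thresholds are explicit,
configurable knobs echoed into every output: "multiple independent
losses" has no canonical quantitative definition, so provenance of the
cutoffs is mandatory. The genus-level call is a declared species pair
(focal host present, congeneric nonhost absent), never inferred.

The permutation test relocates the same number of loss events uniformly
at random over all feasible branch sets and recomputes the co-loss count;
`p = (1 + #{null >= obs}) / (1 + n_perm)`. Feasible sets are mutually
non-nested, leave at least one species outside every event, and contain
no pair of complementary sibling branches — losses on both children of a
bifurcation are indistinguishable under Dollo from one loss on the parent
branch, so they would not be independent events. The trait-loss simulator
samples from exactly the same distribution (rejection sampling, uniform
over feasible sets), which makes observed and relocated events
exchangeable when gene loss is independent of the trait and guarantees
`P(p <= alpha) <= alpha`.

### Orthology classes

Internal gene-tree nodes are labelled by species overlap: a node is a
duplication iff (any pair of) its child subtrees share species; polytomies
are preserved and labelled by the any-pair rule. Species overlap is used
instead of full reconciliation because it requires no species-tree branch
lengths and is the standard conservative criterion; on loss-free trees it
coincides with LCA-mapping reconciliation (verified against that oracle in
the test suite). Gene `r` is an ortholog of gene `f` iff their LCA is a
speciation node — equivalently, walking from `f` toward the root, every
speciation ancestor contributes the leaves of its other subtrees. Per
family the focal species is then classed as:

* `absent` — no focal leaf. Absence is assessed from the tree's leaf set,
  not genome re-search, and carries an `absent_in_tree` caveat flag.
* `multi_copy` — two or more focal leaves.
* `proto_ortholog` — one focal leaf and at least one reference species
  with two or more orthologous genes (reference-side duplication after
  the split from the focal lineage).
* `one_to_one` — one focal leaf and at least one reference species with
  exactly one orthologous gene.
* `unplaced` — one focal leaf but no reference ortholog at all (the gene
  attaches only through duplication nodes). This fifth value exists
  because the four classes above do not cover that topology.

One-to-one and proto-ortholog are *also* stored as independent boolean
flags: different reference species can show different copy numbers for the
same family, so the two conditions overlap (in the demonstration panel
9 of 56 conserved families carry both flags, giving 49 one-to-one and 16
proto-ortholog totals).

Rooting is either on a declared outgroup (smallest side of a bipartition
separating all outgroup leaves) or at the midpoint. Midpoint rooting is
implemented directly (two-sweep diameter search; ties between equally
distant leaves break toward the lexicographically smallest gene id)
because the dendropy implementation misplaces the root on some inputs;
missing branch lengths default to 1.

### Differential expression

The DE caller is deliberately minimal and is documented as *not*
numerically equivalent to full GLM engines; precomputed DE tables are
accepted as an alternative input wherever calls are consumed, for exact
reproduction work. Per two-group contrast (mock vs colonized at one
timepoint):

* median-of-ratios size factors over genes nonzero in every sample;
* NB dispersion alpha estimated per gene by method of moments,
  `(within-group variance - mean) / mean^2`, clipped at zero, then pooled
  across genes (mean over genes whose mean normalized count is at least
  5 — the small-count floor). Pooling matches the generator's shared
  dispersion and keeps the Wald test calibrated at 10 replicates
  (measured type-I error 0.049 at alpha 0.05 under the null simulation);
  a `per-gene` option exists for heterogeneous data;
* delta-method standard error of the log2 ratio of normalized group means
  (means floored at 0.5 to keep zero-mean groups finite), normal-tail p;
* genes with all-zero counts in both groups are flagged untestable,
  excluded from the BH denominator and reported separately;
* BH adjustment; calls use strict inequalities (`log2FC > |1|`, adjusted
  `p < 0.05`), so boundary values are not significant.

The cross-species overlay maps each family's focal gene to its reference
ortholog set; `conserved_induced` requires the focal call up and — under
the default any-up rule — at least one reference ortholog up. An all-up
rule is available. Families carrying calls but missing from the map are
listed in an unmapped report and excluded from all denominators. The core
set intersects `conserved_induced` with the "AM-only / lost-in-nonhost"
coelimination pattern.

### Colonization statistics

Ratios are positives over `n_positions` (default 10 transverse sections)
per replicate and structure; incomplete grids are fatal and name the
replicate and structure. Ratios are analysed untransformed (rank tests
are invariant to monotone transforms) and percent data for the ANOVA path
are used as given, without arcsine transform. Kruskal–Wallis is
tie-corrected with the all-equal case reported as H = 0, p = 1; pairwise
Wilcoxon uses the exact null when both n <= 8 and the pooled sample is
tie-free, otherwise the normal approximation with midranks, tie
correction and continuity correction (the method used is recorded per
pair). Tukey HSD takes p-values from the studentized-range distribution
with pooled within-group variance; all-constant input is a degenerate
no-difference case with a diagnostic flag. Letters come from the
insert-and-absorb compact-letter-display algorithm scanning groups by
decreasing mean; both CLD guarantees (different pairs share no letter,
non-different pairs share one) are brute-force-checked in the tests. The
difference criterion is p < alpha (default 0.05); the source figure
caption prints the inequality the other way around for Wilcoxon, which
context shows to be a typographical slip.

## Synthetic data: what it emulates, and what it does not

The generators emulate the study design this pipeline addresses: a
~59-genome land-plant panel, several independent losses of AM competence,
gene families lost preferentially in nonhost lineages when
symbiosis-linked, a replicated mock-vs-colonized NB count time course at
5, 8 and 11 weeks post-inoculation, and per-section colonization scoring.
Defaults: `base_loss_prob` 0.02 per branch, `coupled_loss_multiplier` 25
(coupled probability capped at 1; an infinite multiplier saturates the
cap), `frac_symbiotic` 0.3, shared NB `dispersion` 0.1, `lfc_location` 2,
`lfc_scale` 0.5, baseline means lognormal(log 100, 1), library-size
factors lognormal(0, 0.15), 3 replicates per group (the study's replicate
count per timepoint is not public; 3 is a stand-in, not a claim), 10
section positions, and 6 replicates per genotype in the colonization
power setting. One global seed expands into per-component child seeds by
a documented scheme (numpy `SeedSequence([seed, crc32(tag)])`), so partial
reruns reproduce the full run.

Simplifications relative to real data: presence/absence is binary (no
pseudogenization gradient), gene loss is per-branch Bernoulli rather than
length-dependent, induction is constant across timepoints, dispersion is
shared across genes, and trees are simulated rather than inferred from
sequences. Passing tests therefore demonstrate correctness of the
inference logic under its own generative assumptions, not robustness to
assembly error, annotation gaps or expression-model misspecification.

The 104-family demonstration panel (`synthetic_panel.py`) is a fully
synthetic stand-in for a curated per-family status table: its trees,
presence patterns and DE tables are constructed so that the pipeline's
own rules recover the headline tallies of the study design it emulates
(56/104 conserved; 49/16 one-to-one/proto; 30 AM-only; 14 genus-lost;
28/56 induced; 25/28 = 89.3% induced in both; ten-family core). All
counts are recomputed from the generated inputs at run time.

## Numerical choices

* Strict inequalities at every DE threshold; BH is monotone and capped
  at 1.
* Non-nested branch sets are sampled by rejection, uniform over feasible
  sets; infeasibility raises an explicit error.
* Yule topologies come from uniform tip splitting (the equal-rates-Markov
  distribution) with iid Exp(1) branch lengths, keeping all branches
  strictly positive.
* Degenerate statistics (all-equal groups, all-zero genes) return the
  no-signal answer (H = 0 / p = 1 / call ns) with flags rather than
  raising.
* Problem sizes used by the heavier checks — 1,000 twelve-leaf Dollo
  oracle cases, 1,000 reconciliation-oracle gene trees, 10,000-unit null
  calibrations, 1,000-family recovery runs — were chosen to give stable
  Monte-Carlo estimates while keeping the whole suite in the minutes
  range.

## Known limitations

* The permutation p-value is conservative when few loss events exist:
  the co-loss count is integer-valued with support {0..k}, so with k = 4
  events the null rejection rate at alpha = 0.05 is far below 0.05
  (measured 0.008 under the trait-independent simulation). A mid-p or a
  finer statistic would trade validity for calibration; the implemented
  formula never exceeds alpha.
* Detection of trait-coupled families requires entire nonhost clades to
  lose the gene; at coupled loss probability 0.5 per branch the per-event
  co-loss probability is ~0.5–0.8, so sensitivity of the coelimination
  flag at k_min = 3 of 4 events is ~0.33 under the default coupled
  conditions (FPR 0.002). Stronger coupling, more loss events, or a
  smaller k_min raise sensitivity; the defaults favour specificity.
* The Wald DE caller assumes a shared dispersion by default and has no
  shrinkage; very small replicate numbers (n = 2–3) rely on the
  cross-gene pooling being appropriate.
* Species-overlap duplication labelling can over-call duplications on
  trees with substantial gene loss or topological error; no
  support-value-based collapsing is applied by default (a threshold hook
  exists in rooting/labelling inputs via pre-collapsed trees).
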