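# Methods

`mztevo` analyses how the pools of maternally deposited and zygotically
transcribed mRNA evolve across a clade of species. Its inputs are
isoform-level FPKM tables from two early embryonic timepoints — one before
zygotic genome activation (stage 2, all transcripts maternal) and one after
(end of stage 5 / late blastoderm) — for each species, a one-to-one ortholog
table, and a rooted phylogeny with branch lengths. This note records the
models, the defaults and why they were chosen, and what the synthetic data
do and do not establish.

## Stage categories

Gene-level FPKM is the sum of the FPKM of a gene's isoforms, per sample, and
presence at a stage means mean-replicate FPKM ≥ 1 (the threshold is
inclusive: 1.0 counts as present). Each feature (isoform or gene, always
classified at its own level, never mixed) receives exactly one of six
categories:

| category | rule |
|---|---|
| M  | present at stage 2 only (maternal-only) |
| Z  | present at stage 5 only (zygotic-only) |
| PM | present at both; stage 2 ≥ 2 × stage 5 and q < 0.05 |
| PZ | present at both; stage 5 ≥ 2 × stage 2 and q < 0.05 |
| MZ | present at both, predominant at neither |
| N  | present at neither |

The rules are symmetric: swapping the two stage means maps M↔Z and PM↔PZ
and fixes MZ and N, a property the suite fuzz-tests.

**Significance.** The predominance call needs a per-feature q-value for the
stage contrast. The original differential-expression machinery for such
data operates on read counts, which this package deliberately does not
consume; instead the default is a two-sided Welch t-test on log2(FPKM + 1)
replicate values, Benjamini–Hochberg adjusted across all features of a
species. An exact permutation test on the mean log2 difference is available
(`method="permutation"`) but is intentionally not the default: with the
typical 3 replicates per stage it enumerates only 20 assignments and its
two-sided p can never fall below 0.1, so PM/PZ would be unreachable at
α = 0.05. Features with fewer than two replicates at either stage get no
q-value and can never be called PM/PZ. Replicate rows with zero variance are
handled explicitly (p = 1 when the means agree, p = 0 otherwise) so that
noiseless data classify deterministically.

**ALT genes.** A gene whose isoform calls include at least one
maternal-class (M or PM) and at least one zygotic-class (Z or PZ) isoform is
flagged ALT — stage-specific isoform usage. The flag is monotone: adding an
isoform call can never revoke it.

**Unique representation.** Screening for species-specific expression uses
two thresholds with deliberately different strictness: the focal species
must exceed FPKM > 3 (strict inequality), every other non-blank species must
sit below the presence threshold (FPKM < 1). Blank orthologs are skipped,
not treated as absent.

## Cross-species comparison

Species are compared on ortholog groups with one-to-one orthologs in at
least 12 of 14 species (configurable). Correlations are Spearman's rank
coefficient; a constant vector makes rho undefined and it is reported as
absent, never imputed as 0. Because Spearman depends only on ranks, whether
FPKM is log-transformed first is immaterial; the suite verifies invariance
under strictly increasing transforms. Stage-restricted comparisons support
two selection modes — genes with the category in *both* species of a pair,
or in *at least one* — and compare the FPKM means of the stage the category
refers to (maternal classes at stage 2, zygotic at stage 5). Groups with a
blank ortholog in either species of a pair are excluded pairwise, not
listwise across all species.

Hierarchical clustering of the species × stage condition matrix uses
distance 1 − rho with average linkage. The upstream tooling this mirrors
leaves both choices implicit; they are pinned here (and recorded in the
clustering output metadata) because reproducibility requires one fixed
choice. Listwise-complete rows feed the correlation matrix so every
condition pair uses the same gene set.

Fisher exact tests (category enrichment of gene subsets) use the standard
two-sided hypergeometric convention; the suite checks the p-values against
an exhaustive enumeration of all 2×2 tables with grand total ≤ 30 to 1e-12.
Structure comparisons (exon count, exonic/intronic length for M∪PM vs Z∪PZ)
use two-sided Mann–Whitney rank-sum tests.

## Ancestral reconstruction

Transcript presence per (gene, stage) is a binary character over species:
1 if mean FPKM ≥ 1, 0 otherwise, unknown where the ortholog is blank.
Characters evolve under the two-state Mk model with gain rate q01 and loss
rate q10 per unit branch length; transition probabilities have the
closed form given in `mztevo.ancestral`. Design choices, all open in
principle and fixed here:

* **Fixed input tree, empirical Bayes.** The tree is an input, never
  inferred. Rates are fitted by maximizing the summed pruning
  log-likelihood over all characters of a stage (one shared rate pair per
  stage — a single character cannot identify two rates), and node
  posteriors are then exact marginals under the fitted model. This replaces
  MCMC co-estimation with a deterministic computation; the event-calling
  logic downstream is unchanged.
* **Root prior** is the stationary distribution of the fitted rates,
  leaving no free parameter.
* **Rate bounds** [1e-6, 1e3] per unit branch length; an estimate at a
  bound (e.g. all-constant characters) emits a warning rather than an
  error. Optimization is L-BFGS-B over log rates from a (1, 1) start; the
  likelihood surface for two bounded rates is well behaved at the sample
  sizes involved (the suite checks 20% relative recovery at 2,000
  characters).
* **Event calling**: a gain on a branch requires posterior ≥ 0.90 for
  absence at the parent and ≥ 0.90 for presence at the child; a loss is the
  mirror image; at most one event per branch per character. Terminal
  branches are eligible (an observed tip is posterior 1 on its state);
  branches ending in an unknown tip are skipped. Raising the threshold can
  only remove events.
* **Numerics**: partial likelihoods are max-rescaled per node with a log
  accumulator; outside messages are renormalized per character, so
  posteriors are stable for arbitrary branch lengths. Impossible data
  (e.g. conflicting tips on zero-length branches) give −inf log-likelihood
  and NaN posteriors rather than an exception.

Two independent oracles guard the implementation: brute-force enumeration
over all internal-state assignments (`brute_force_marginals`, exact for
small trees) and the parsimony limit — as rate × tree height → 0, MAP
marginal states must agree with the state at every node that is uniquely
determined across all most-parsimonious reconstructions
(`mpr_state_sets`, exhaustive). Note that first-pass Fitch state sets are
*not* the right comparison at non-root nodes: they do not enumerate the
states attained by most-parsimonious reconstructions, and using them
depresses apparent agreement by about one node per hundred.
`fitch_parsimony` is retained as the minimum-change-count oracle.

## Conserved core sets

For a stage-restricted category (zygotic-only by default; maternal-only
through the same code), the *loose* conserved set holds genes with the
category in a distant outgroup and ≥ 1 ingroup species; the *core* set
additionally requires the basal ingroup species and ≥ 1 member of a
designated early-diverging subgenus pair. Core ⊆ loose always. The
"mean additional species" summary excludes the species that established
membership: outgroup plus the single qualifying species for the loose set;
outgroup, basal, and every qualifying subgenus member for the core set.
Species with unknown calls count in neither numerator nor denominator.

## Synthetic data

The generator produces the full input bundle (expression TSVs, sample
sheet, isoform map, ortholog table, tree) plus truth tables (per-species
category and ALT flags, internal-node states, branch events). Defaults were
fixed once to mirror the study conditions the pipeline targets:

* **Tree**: a bundled 14-tip phylogeny with a melanogaster-subgroup-like
  clade (two sister pairs), an ananassae-like lineage, an obscura-like
  trio, a basal tip and a distant two-tip subgenus clade; unit-free,
  roughly clock-like branch lengths (height ≈ 0.45).
* **Rates** q01 = 1.0, q10 = 0.307 per stage, root prior stationary, so
  π1 = 0.765; with orthologs blanked independently at rate 0.0656 the
  expected observed character frequencies are (present, absent, unknown) ≈
  (0.715, 0.219, 0.0656), the profile the analysis assumes. The two stage
  characters of a gene evolve independently.
* **Expression**: present genes draw a per-(gene, species) lognormal level
  with log-mean 3 and log-sd 1 (median FPKM ≈ 20); replicates (3 per stage)
  are multiplied by mean-1 lognormal noise with CV 0.2; absent genes are 0
  with a 10% chance of a uniform(0, 0.5) sub-threshold leak.
* **Archetypes**: 10% of genes are ALT (realized, where present at both
  stages, as one stage-2-only and one stage-5-only isoform at a common
  level); a further 10% are predominant at one stage with an 8-fold design
  ratio — far above the 2-fold calling bar so that detection is limited by
  the significance test, not the ratio; remaining genes split their level
  across 1–3 isoforms with stage-constant Dirichlet proportions, which by
  construction can never fake an ALT pattern.
* **Truth labels** are derived by applying the classification rules to the
  designed (noiseless) stage means, with "significant" meaning the designed
  means differ. This makes zero-noise recovery exactly 100% by definition of
  correctness, and makes the noisy-recovery figures honest measures of the
  classifier under replicate noise.

What the simulation does *not* emulate: read-level sampling noise and its
mean–variance relationship, normalization artifacts, correlated evolution
between the two stage characters, rate variation across genes or branches,
lineage-specific expression drift (present-state levels are drawn
independently per species rather than evolving along the tree), or
mis-annotation of orthologs beyond random blanking. Passing recovery tests
therefore demonstrates the correctness of the pipeline's logic and its
robustness to replicate noise at realistic magnitudes — not performance on
real sequencing data.

## Problem sizes

The test suite and the acceptance script size their simulations to keep the
whole run in the low tens of seconds while leaving comfortable statistical
margins: 8,075 ortholog groups for the character-coding arithmetic, 100
random 3–6-tip instances for the enumeration oracle, 1,000 6-tip characters
for the parsimony limit, 300 genes × 14 species for noiseless recovery,
2,000 genes × 14 species (≈ 26,000 gene-species calls, ≈ 49,000 confident
node calls) for noisy recovery and posterior calibration, 10,000 fuzzed
classifier inputs, and all ≈ 44,500 non-degenerate 2×2 tables with total
≤ 30 for the Fisher check.

## Known limitations

* The Welch-based q-values are a replicate-level stand-in and are not
  numerically comparable to count-based differential-expression q-values;
  only the calling rule (2-fold and q < 0.05) is shared.
* With 2 replicates the Welch test is legal but weak; PM/PZ calls then
  depend heavily on the BH pool.
* Rates are shared across characters within a stage; genes with atypical
  turnover are reconstructed under the genome-wide rates.
* The marginal reconstruction reports per-node posteriors; it does not
  produce joint (max-joint) reconstructions or event times along branches.
* `min_species` filtering interacts with blanking: groups can pass the
  filter yet still be unknown in a species used by a conservation role, in
  which case they simply cannot qualify for that set.
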