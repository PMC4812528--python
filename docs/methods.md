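# Methods

`pathrisk` implements an integrative, pathway-level analysis of familial
breast cancer (FBC) susceptibility: supervised classification of blood-cell
expression profiles restricted to one pathway at a time, a germline rare-variant
filtering and collapsing cascade tested with an unconditional exact test,
rank-based combination of per-pathway evidence across cohorts and data
types, and quantitative fluorescence morphometry of primary mammary
epithelial cells. This note records the models, the parameters that matter,
the numerical choices, and what the synthetic benchmarks do and do not show.

## Pathway classification

For a pathway with member genes measured in a cohort, the question is
whether the joint expression of those genes distinguishes women who
developed FBC from family-history women who did not.

**Gene ranking.** Genes are ranked by SVM recursive feature elimination:
each round fits a linear soft-margin SVM on the surviving genes
(z-scored), scores each gene by its squared weight, and removes the lowest
10% (`rfe_fraction`); once fewer than 1% of the initial genes remain
(`rfe_single_gene_cutoff`), exactly one gene is removed per round. The
reversed elimination order is the ranking. The ranking model uses heavy
regularization (`rfe_c = 0.05`): with ~80 samples and tens to hundreds of
correlated genes, a hard-margin fit gives noisy weight orderings, while a
strongly regularized fit recovers planted signal genes far more reliably
(all 5 of 5 planted genes in the top 10 in 100/100 simulation seeds at
C=0.05, versus ~95/100 at C=1). Constant genes receive zero weight and are
eliminated first; ties break by input order, so results are deterministic.

**Gene count.** Cross-validated AUC is evaluated for the top 25, 50, 75,
..., 300 ranked genes (`gene_count_grid`); grid points above the pathway
size collapse to the full set, and ties resolve to the smallest count
(parsimony). The same seeded folds are reused across the grid so the AUCs
are comparable.

**Classification.** Per-sample scores come from an RBF-kernel SVM in a
stratified 10-fold cross-validated design (leave-one-out for the small
breast-tissue datasets), so each sample is scored by a model never trained
on it. The soft-margin parameter C is tuned per outer fold by inner
stratified cross-validation over `c_grid = {0.01, 0.1, 1, 10, 100}`
(held-out AUC; smallest C on ties). The RBF bandwidth is set by the median
heuristic — gamma = 1 / median squared pairwise distance — on training-fold
data. Gene z-scoring uses training-fold statistics only. Decision values
are mapped to [0,1] scores by a Platt-style sigmoid fitted on the training
folds; because the map is strictly monotone, AUC and permutation P-values
are identical whether computed from decision values or calibrated scores,
and the hot loops use raw decision values.

**AUC and significance.** AUC is the Mann-Whitney pairwise probability
(ties count one half) with a DeLong 95% confidence interval. The empirical
P-value for a pathway is the fraction of label permutations (default
B = 1,000) whose recomputed cross-validated AUC strictly exceeds the
observed one; the plain fraction is reported (it can be exactly 0), with
an optional (r+1)/(B+1) correction off by default. Each permutation
re-draws stratified folds for the shuffled labels, so the permuted
statistic is the same function of (data, labels) as the observed one —
this is what makes the null uniform. By default permutations reuse the
observed gene panel and the C policy; `perm_refit` re-runs ranking and
gene-count selection inside every permutation at ~100x the cost.

**Treatment-effect filter.** A pathway whose scores differ (two-sided
Welch t-test, P < 0.05) between family-history women who never developed
cancer and women without a family history — over half of whom had treated
sporadic cancers — is flagged: its apparent signal may reflect treatment
history rather than germline susceptibility. The filter is applied once,
on the training cohort. If either comparison group has fewer than two
samples the flag is indeterminate and the pathway is retained.

## Confounder screen

Before pathway mapping, genes whose expression tracks immune composition
or clinical/lifestyle covariates are removed. For each covariate factor a
joint linear model (multifactor ANCOVA) is fit on the samples where the
factor is observed; co-adjusting covariates enter only when fully observed
on those samples, which handles the block-missing pattern of survey data
(surveys typically cover a subset of a cohort) without collapsing to a
tiny joint complete-case set. A factor's P-value is a type-II F-test
(extra sum of squares of the factor's one-hot block given the others), so
term order does not matter; a gene is blacklisted if any factor attains
P < 0.01. The screen is intentionally uncorrected for multiple testing —
it is a conservative exclusion filter, not an inference — and the
blacklist is monotone in the threshold.

## Variant cascade and pathway burden

Annotated germline variants pass a fixed-order cascade; each excluded
variant is attributed to the first rule it fails, so the per-rule counts
and survivors always sum to the input:

1. reference-population MAF > 1% (any population) — drop;
2. background-cohort MAF > 3% (a higher bar, since a cancer-enriched
   background may itself carry susceptibility variants) — drop;
3. carried by > 15% of study samples (carrier fraction, not allele
   frequency) — drop;
4. outside primary-transcript exons ± 2 bp (splice-site allowance) — drop;
5. severity/effect rules: MODIFIER and LOW severities drop; HIGH always
   retained; MODERATE InDels retained; missense SNVs retained only when
   the aggregated deleteriousness call is "deleterious" ("neutral" and
   remaining MODERATE SNVs drop);
6. missense SNVs with no deleteriousness call drop by default
   (configurable).

Heterozygous and homozygous carriage are equivalent. Survivors collapse to
a binary samples x genes matrix (any retained variant = mutated) and then
to samples x pathways by OR over member genes.

**Frequent-gene exclusion.** Genes mutated in more than a threshold
fraction of a background germline cohort are removed (except BRCA1/2)
before pathway collapsing, on the premise that commonly mutated genes are
unlikely to drive susceptibility. The threshold is chosen from the
excluded-gene-count curve over an even grid of candidate thresholds
(default 0.2%-10%, 50 points): the lower endpoint of the largest drop
between adjacent candidates, ties to the smallest. The full curve is
returned so the choice is auditable.

**Burden test.** Pathway mutation rates between groups are compared with a
one-sided unconditional (Barnard) exact test. The score statistic (pooled
Wald) is computed for every achievable 2x2 table; the P-value is the
supremum over the common success probability pi of the total probability
of tables at least as extreme as the observed one. The supremum is located
on a pi grid of 0.001..0.999 (step 0.001) and sharpened by bounded local
optimization to xatol = 1e-12; the grid comfortably resolves the modes of
the polynomial objective at the sample sizes involved. When the observed
table is the least extreme possible, the P-value is exactly 1. The
BRCA1/2-vs-BRCAX subgroup comparison applies the test once in each
direction. The implementation agrees with a brute-force enumeration oracle
to < 1e-6 over all tables with group sizes up to 8, and with an
independent library implementation of the same construction.

## Combining evidence

Per-dataset pathway P-values are combined by rank consistency: within each
dataset pathways are ranked by ascending P (average ranks on ties), ranks
scale to (0,1) as (rank - 0.5)/N, and a pathway's mean scaled rank over
its m observed datasets is referred to the exact Irwin-Hall distribution
of a mean of m uniforms (the normal limit is used beyond m = 20, where the
alternating series loses precision; at small m the normal approximation
overstates deep-tail P-values by orders of magnitude, which matters
precisely for the top-ranked pathways this statistic exists to find).
Pathways missing from a dataset are combined over their observed m and
flagged, not imputed. The statistic depends only on within-dataset ranks,
so it is invariant to monotone recalibration of any dataset's P-values.

Alternative combiners for robustness checks: Fisher's combined probability
(-2 sum log p against chi-square 2m), Wilkinson's minimum-P (Beta(1, m)
tail; the order statistic k is configurable, k = 1 by default), and
Edgington's sum of P with the exact Irwin-Hall tail. All reduce to the
identity at m = 1. Multiplicity is handled by Storey q-values: pi0
estimated on the lambda grid 0.05..0.95 (step 0.05) with a cubic smoother
evaluated at lambda = 0.95 and clamped to (0, 1], then the monotone
step-down transform. q-values are never larger than Benjamini-Hochberg
adjusted P-values.

**Candidate funnel.** Candidates are pathways observed in every required
dataset with combined rank P below alpha (default 0.05), minus pathways
flagged by the treatment-effect filter or the BRCA subgroup comparison.
The funnel reports counts after each step; they are non-increasing by
construction.

**Mutation-expression concordance.** For samples profiled on both
platforms, each shared gene's binary mutation status is correlated with
its expression (Spearman). Correlations are Fisher-transformed and scaled
by sqrt(n-3); the local false discovery rate is estimated by central
matching — empirical null location and scale from the median and central
interquartile range, marginal density by Gaussian KDE, pi0 by matching at
the null center — and genes with local FDR <= 0.2 (configurable) are
selected. Genes with constant mutation vectors are skipped and counted.

## Morphometry

Each field has three channels: F-actin (phalloidin), focal adhesions
(vinculin), nuclei (DAPI). Cell area is segmented from the summed
actin+adhesion signal: 8-bit conversion with full-range contrast stretch,
Otsu threshold, morphological closing (disk radius 3), hole filling. The
stretch is deliberately min-max rather than percentile-clipped: nuclei and
sparse cells can cover under 2% of a field, and percentile clipping would
rescale background noise to full range. Nuclei are counted by binarizing
the DAPI channel, then marker-controlled watershed on the distance
transform to split touching nuclei, with a minimum particle area of 30 px
at the synthetic scale (configurable). The cell-size metric is
100 x (cell area fraction) / (nuclei count) — percent of field per nucleus.
Cell density is summarized by the three smallest pairwise inter-nucleus
center distances. Stain fractions subtract the median intensity outside
the cell mask as background (a median-filter rolling-ball analog is
available as an option; a fixed-radius filter erases stain regions larger
than its radius, which breaks the limiting case of a stain covering the
whole cell), then threshold on within-mask intensities with an exact-value
Otsu — the stain channel is trimodal (background, diffuse cell signal,
bright stain) and a global histogram Otsu merges the wrong modes. Group
comparisons are two-sided Welch t-tests with fields, not patients, as the
unit; per-patient aggregation is available.

## Synthetic data

The generator emulates the statistical structure of the study's deposited
datasets without access to them. Defaults are the study conditions:

- **Cohorts**: 40 familial cases + 40 family-history controls per cohort
  (mirroring the 83-sample family-history training set), plus 20
  no-family-history controls of whom 55% developed sporadic cancer
  (mirroring the 41-woman control arm); ~40% of family-history women are
  BRCA1/2 carriers, the rest BRCAX, allocated deterministically so strata
  counts are exact.
- **Expression**: 100 disjoint pathways of 20-40 genes; within-pathway
  exchangeable correlation 0.2; effect size 1.0 SD added to 30% of member
  genes of 5 causal pathways, in familial cases only — so the
  no-family-history arm stays null and the treatment filter's false-flag
  rate is its nominal 5%. Effects are additive on an already-normalized
  Gaussian scale; no microarray noise model is simulated.
- **Covariates**: three numeric clinical covariates observed on half the
  cohort (the survey-coverage regime), with 2% of genes linked to one of
  them at 0.8 SD per covariate SD.
- **Variants**: per-gene carriage Bernoulli(0.002) (so a 25-gene pathway
  is mutated in ~5% of samples, matching the null side of the burden
  comparison); in causal pathways each familial case carries a variant in
  one random member gene with probability 0.35 (the enriched side).
  Mutation is per-gene Bernoulli with no linkage, matching the binarized,
  multiplicity-free representation the cascade produces. Clean variants
  are rare/exonic/HIGH so they survive the cascade; two decoys per rule
  fail exactly one rule each. The background frequency table holds 10
  non-causal genes at 5% against a 0.1% base, giving a known breakpoint
  for threshold selection.
- **Fields**: 256x256 px, 10-14 nuclei of radius 6. Clustered-small:
  nuclei packed around the field center, cell footprint radius 12, 35%
  actin coverage. Dispersed-large: nuclei spread with minimum spacing,
  footprint radius 22, 60% actin coverage. Ground truth (centers, exact
  mask-derived area and stain fractions) is recorded from the constructed
  geometry, not analytic formulas, so overlap effects are included.

Every generator is deterministic given (config, seed); cohort labels and
stages derive child seeds (a counter/hash scheme) so the same pathway
structure underlies all cohorts of a study and stages can be re-run in
isolation.

What passing synthetic benchmarks shows: the machinery is calibrated under
its stated null (permutation P uniform, exact tests conservative, local
FDR selects ~nothing under independence) and recovers planted structure at
the study's effect sizes. What it does not show: robustness to microarray
batch structure, pathway overlap and gene multi-membership, linkage
between variants, population stratification, or real staining artifacts —
none of which the generator emulates.

## Problem sizes in the shipped benchmarks

The test suite and the acceptance script run the null calibration at 250-500
replicates with B = 199 permutations, the planted-recovery study at 100
pathways x 2 cohorts with B = 49, and the exact-test sweep over all 2x2
tables with group sizes up to 8 (tests) or 6 (script). These sizes give
binomial standard errors well inside the asserted bands while keeping a
full run of the pipeline in the minutes range on one CPU.

## Known limitations

- Gene identity is by uppercased symbol; no alias resolution.
- Pathways are unweighted gene sets; no topology.
- The permutation default reuses the selected gene panel; selection-aware
  nulls cost ~100x more (`perm_refit`).
- The Barnard test enumerates (n1+1)x(n2+1) tables; group sizes in the
  thousands would need a different algorithm.
- The local-FDR empirical null assumes the central bulk of genes is null;
  pervasive true signal would bias pi0 and the selection.
- The treatment filter and subgroup exclusion are hypothesis filters at
  alpha = 0.05; they remove ~5-10% of genuinely causal pathways by chance,
  which the funnel report makes visible.
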