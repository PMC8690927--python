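# Methods

## Data model

The substrate of all mutation analyses is a ternary sample × gene status
matrix: mutant (1), wild-type (0) or not assayed (NA), plus an optional
per-sample count of non-synonymous mutations.  The NA state is first-class
because realistic multi-cohort tables mix whole-exome/-genome samples with
targeted panels; in particular gene fusions (the `FGFR2_fusion`
pseudo-gene, kept distinct from FGFR2 point mutations) are typically not
assessed in every sample.  Every pairwise statistic therefore uses
pairwise-complete denominators: a sample enters a gene pair's 2×2 table
only when both genes were assayed.

Cohort-level cleaning applies two filters in a fixed order.  First,
hypermutators — samples with more than 300 non-synonymous mutations — are
removed (samples without a count, i.e. panels, are exempt; the rule has
nothing to act on).  Second, genes are kept when assayed in at least 70%
of the remaining samples **and** mutated in strictly more than 2% of the
assayed samples.  The order matters because gene frequencies are
recomputed after hypermutator removal; a test pins the order.

## Pairwise co-occurrence / mutual exclusivity

For each unordered gene pair the sample odds ratio
OR = (n₁₁·n₀₀)/(n₁₀·n₀₁) is reported, with 0 or +∞ for zero cells and no
continuity correction — the cross-product estimate, not the conditional
MLE; the published validation odds ratios are reproduced exactly by this
choice on the tables recovered from their margins.  Significance is a
two-sided Fisher exact test (sum of hypergeometric probabilities no larger
than the observed table's), and Benjamini–Hochberg step-up q-values are
computed over the family of all pairs tested in one run.  Network edges
require q strictly below 0.05 and an odds ratio different from 1; a pair
whose OR is exactly 1 (or undefined, 0/0) carries no direction and never
forms an edge.

BH q-values are monotone along the sorted p-values, bounded below by p and
equivariant under permutation of the input; these are the invariants the
property tests assert.  (Literal idempotence — BH applied to its own
output returning the same values — does not hold in general: for
p = (0.1, 0.5) the q-values are (0.2, 0.5) but re-adjusting gives
(0.4, 0.5).  The tests therefore do not assert it.)

Set-level exclusivity between the Cluster1 and Cluster2 gene sets is
computed on per-sample indicators: a set is mutant when any member is
mutant, NA when a member is unassayed and none is mutant (wild-type status
of the set cannot be asserted), wild-type otherwise.  When stratified by a
clinical covariate, one table is produced per stratum level and p-values
are reported raw — the strata are a small, pre-specified family and the
comparison of interest is between odds ratios, not their individual
significance.

## Cluster rules

Assignment is a total, deterministic function of the seven gene states:

1. **C1** iff any of KRAS/TP53/SMAD4 is mutant (irrespective of anything
   else, so Cluster1/2 double mutants stay in C1 and are flagged
   `co_mutant` for the stage-enrichment analysis);
2. else **C2** iff any of IDH1/IDH2/FGFR2_fusion/BAP1 is mutant;
3. else **C3** iff all seven are assayed and wild-type;
4. else **UNCLASSIFIED** — an unassayed gene with no observed mutation
   leaves wild-type status unprovable, so such samples are not forced into
   C3.

Sub-clusters: within C1, 1A iff KRAS mutant, else 1B; within C2 the
precedence is 2A (IDH1/2) > 2B (FGFR2 fusion) > 2C (BAP1 only).  Tumour
mutational burden is compared between groups with two-sided Mann–Whitney
tests — exact enumeration when both groups have ≤ 8 observations, the
tie-corrected normal approximation otherwise.

## CP score

One point each for S100P IHC positivity, KRT17 IHC positivity and CA19-9
≥ 100 U/ml (the cut-off is inclusive); 0–1 is "low", 2–3 "high"; any
missing marker makes the score missing — no partial-score imputation is
attempted.  Cluster-prediction performance treats genomic C1 as the
positive class with "high" = score ≥ 2 as the operating point; the ROC
sweeps all integer thresholds of the ordinal score and AUC is the
trapezoid over its points (a constant score yields AUC 0.5 by
construction).  Among C3 samples the score defines the modified clusters:
high → classical-like, low → progenitor-like.

## Expression signatures

The per-sample enrichment score of a signature is the mean across-sample
z-score of its up genes minus that of its down genes.  This deterministic
mean-z form was chosen over rank-based single-sample GSEA: it is exactly
location-invariant per gene, flips sign under up/down swap, and has a
closed-form expectation under planted shifts, all of which the tests
exploit.  Zero-variance genes contribute z = 0; signature genes absent
from a matrix are skipped and reported.  Two scores classify samples into
three groups with a margin rule (|difference| ≤ 0.2 → "mixed"; the margin
is a configuration knob — the boundary of "mixed" is otherwise arbitrary).

Differential expression between groups uses per-gene Welch t-tests on
log2 values with the linear fold change 2^(Δ mean); genes constant in both
groups get p = 1 by convention.  The cross-dataset consensus keeps genes
with fold change > 2 in a consistent direction and p < 0.05 in **every**
dataset, and flags as top discriminators those with mean fold-change
magnitude > 4.

## Methylation

Differential probes between IDH1/2-mutant and wild-type samples: Welch
(unequal-variance) t-test per probe on raw β-values, BH FDR at 5% across
all tested probes, then an effect filter |Δβ| ≥ 0.20 on the group-mean
difference.  Both the test and the filter deliberately act on β rather
than M-values, matching how the thresholds are defined.  Probes with more
than 20% missing entries are dropped at load.  Sample-level IDH-like
calling is nearest-centroid by Pearson correlation over the retained
probes (ties go to non-IDH-like); a heatmap-style grouping could equally
have been used, but the centroid classifier is deterministic and
parameter-free given the probe set.

## Survival

Kaplan–Meier product-limit curves with the median defined as the smallest
time at which S(t) ≤ 0.5 (undefined when never reached); k-sample log-rank
tests; Cox proportional hazards by partial likelihood with Efron tie
handling (the library default — no tie method is otherwise mandated),
reporting hazard ratios with 95% CIs.  Stage and CA19-9 enter Cox models
as dichotomies (I/II vs III/IV; < 100 vs ≥ 100 U/ml).  Degenerate designs
(constant covariate, too few events) raise explicit errors rather than
returning unstable fits.

## Synthetic cohort generator

The generator is cluster-first: each sample draws a latent sub-cluster
label from mixing proportions π, then its seven gene states conditionally
independently given the label, renormalised over genotypes where the
label's defining set carries at least one mutation.  Because each
sub-cluster is an explicit finite mixture over the 2⁷ genotype patterns,
the pairwise joint probabilities — and hence the odds ratio any
co-occurrence analysis should converge to — are available exactly
(`analytic_pair_or`), which is what makes the generator an oracle rather
than just a smoke-test fixture.

Defaults encode the emulated study conditions and are chosen once:

- π = (1A .199, 1B .132, 2A .116, 2B .058, 2C .058, C3 .437), reproducing
  the reported 33.1% Cluster1 / 23.2% Cluster2 prevalence in a
  whole-exome discovery cohort;
- per-gene co-mutant leak 0.01 (each opposite-set gene mutates with this
  probability), giving ≈ 2.0% Cluster1/2 double mutants against the
  reported 2.1%;
- co-mutants draw stage III/IV with probability 0.875 (reported 14/16);
- FGFR2-fusion assayed in 90% of samples, emulating incomplete fusion
  coverage; 2% hypermutators with counts 301 + Poisson(250);
- TMB means 60 / 120 / 45 (1A / 1B / others) so Cluster1B carries the
  highest burden; CA19-9 log-normal medians 300 / 150 / 30 / 80 U/ml for
  1A / 1B / C2 / C3; IHC positivity, histology, region, etiology and
  metastasis rates graded C1 > C3 > C2; OS Weibull scales 20 / 55 / 38
  months for C1 / C2 / C3 (shape 1.1, administrative censoring by 60
  months), RFS at 0.6× the OS scale.

Expression planting: signature genes shift by +1 log2-SD in their cluster;
the S100P/KRT17 discriminators shift by +3 log2 units in IHC-positive
samples, coupling transcript and protein marker.  Methylation planting:
differential probes have probe-specific base levels (uniform 0.30–0.55)
and alternate hyper-/hypo-methylation of ±Δβ (default 0.25, σ = 0.05) in
IDH-mutant samples — the alternation gives the two centroids distinct
shapes so that correlation-based classification is well posed, which a
uniform same-direction shift would not.

What the generator does **not** emulate: per-variant effects (only
per-gene status), copy number and structural variation beyond the fusion
pseudo-gene, batch effects and platform noise in expression, cell-type
composition of methylation, informative censoring, or correlations between
modalities beyond the shared cluster label.  Passing tests therefore
demonstrate correctness of the statistical machinery under the posited
cluster-mixture model, not robustness to every artefact of real cohorts.

All randomness flows from one seed fanned out per data modality via
`numpy.random.SeedSequence`, so identical configs are bit-identical and
modalities can be regenerated independently.

## Numerical and testing choices

- Fisher p-values are validated against exhaustive hypergeometric
  enumeration over *all* 2×2 tables with n ≤ 30; BH against the literal
  quadratic-time step-up definition on 1,000 random vectors.
- The null calibration check simulates independent genes (10 genes at 50%
  frequency, n = 400, 20 replicates) and requires the q < 0.05 edge rate
  to stay within 3 standard errors of nominal.
- The simulator-vs-oracle convergence check runs at n = 50,000 on a
  convergence-test configuration that equals the defaults except for a
  co-mutant leak of 0.15, and compares only pairs whose delta-method
  standard error of the log odds ratio (computed from the analytic cell
  probabilities, before any data are drawn) is at most 0.03 — at this n a
  10% relative band is then a ≥ 3σ margin.  Under the study-condition
  leak of 0.01 the cross-set double-mutant cells have expected counts near
  100, where a 10% band on a single draw is only a ~1σ statement and a
  "failure" would carry no information about correctness; the screen keeps
  the check powerful against real implementation errors instead of noisy.
  Marginal frequencies are checked to ±0.01 for every gene without any
  screen.
- Planted-effect recoveries use fixed seeds: Δβ = 0.25 probes at 30/30
  samples (exact set recovery), a hazard ratio of 2 at n = 500 (estimate
  within [1.7, 2.35]), and exact cluster-label recovery at zero co-mutant
  leak.
- Problem sizes throughout the suite (hundreds to tens of thousands of
  samples) were chosen so each check has conventional power while the full
  suite stays interactive on a laptop.

## Known limitations

- The enrichment score is not rank-based; cohorts with heavy-tailed
  expression may prefer an ssGSEA-style variant, which is out of scope.
- The pairwise framework is marginal Fisher testing; background-rate-aware
  exclusivity methods (DISCOVER, WExT) are deliberately not implemented.
- The CP-score ROC treats the score as an ordinal 0–3 sweep; with only
  four thresholds the AUC is coarse by construction.
- `UNCLASSIFIED` handling of incompletely assayed, otherwise wild-type
  samples is a design decision of this package; analyses that force such
  samples into Cluster3 will report slightly different Cluster3 sizes.
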