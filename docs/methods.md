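# Methods

This note documents the models and procedures implemented in `wtme`, the
choices made where the procedure definitions were genuinely open, and what
the synthetic-data validation does and does not establish.

## Signature scoring (ssGSEA)

For each sample, genes are ordered by descending expression on the
log₂(TPM+1) scale, with ties broken ordinally by gene id so the ordering —
and therefore every score — is fully deterministic.  For a gene set *S*,
two cumulative curves are walked down the ordering: the weighted fraction
of in-set genes seen so far, with the gene at position *i* weighted
`(N−i+1)^α`, and the unweighted fraction of out-of-set genes.  The
enrichment score is the sum of their differences over all *N* positions
(the area between the curves).  `α = 0.25` by default, the convention of
single-sample enrichment tooling; it is exposed because the source
procedure does not pin it down.  Optional normalization divides all scores
of a profile by its global max − min.  Being rank-based, scores are
invariant to monotone transforms of a sample's expression; the test suite
verifies exact equivalence with an independent brute-force scorer that
materializes both curves step by step, exhaustively over all gene subsets
of matrices up to 8 genes × 3 samples.

Set genes missing from a matrix are dropped with a logged count rather than
imputed; a set with no gene present is an error.  Purity adjustment divides
a sample's scores by (1 − purity) — two samples with identical non-tumor
composition but different tumor content then score comparably — and is
undefined at purity 1, which is an error rather than a clipped value.  The
TLS-style geometric-mean score uses exp(mean(log(TPM+1)))−1 so that a
single zero-TPM gene does not annihilate the product while equal inputs
remain a fixed point.

## Preprocessing

Counts→TPM divides by gene length in kb and rescales each sample to 10⁶;
an all-zero sample leaves the normalization undefined and is an error
naming the sample.  The log transform is log₂(x+1) (zeros exist in TPM).
Variable-gene selection keeps the upper decile of per-gene median absolute
deviations, with the count defined as ⌈0.1·n⌉ and boundary ties broken by
gene id; the 1.4826 MAD consistency constant is applied (irrelevant to the
ranking, documented for reproducibility).  The purity filter removes
samples with purity strictly above 0.98 — near-pure tumors carry too little
microenvironment signal for the scores to be stable.

## Consensus subtyping

Each of `n_perturbations` (default 500) perturbations draws 90 % of
features and 90 % of samples without replacement, computes 1 − Pearson
correlation distances between samples over the drawn features, and cuts a
Ward-linkage tree at *k*.  The consensus entry for a sample pair is the
fraction of perturbations that drew both *and* co-clustered them
(pair-count normalization); pairs never drawn together default to
consensus 0, and a sample never co-sampled with any other is an error
advising more perturbations.  Final labels come from a Ward tree on
1 − consensus, cut at *k*, with cluster ids assigned by decreasing size for
determinism.  For *k* = 2 microenvironment profiles, the cluster with the
lower mean enrichment across all cell types is named dWT and the other iWT;
an exact tie is flagged unresolved, never guessed.  A degenerate
configuration (fractions 1, one perturbation) reduces exactly to a single
plain hierarchical clustering.

Correlation distance is scale-invariant per sample, so clustering is
identical on raw and purity-adjusted profiles; the pipeline clusters the
adjusted profile, which is also what is reported.

## Subclass mapping

Whether subtypes found independently in two cohorts are "the same" is
assessed by mutual marker-gene association.  For subclasses (a, b): the
top `n_marker_genes` signal-to-noise markers of *a* (computed in cohort A
over the shared gene universe) are scored by their mean signal-to-noise in
cohort B's *b*-vs-rest contrast; a null distribution comes from permuting
B's labels.  The mirrored direction is computed likewise, and the pair's
p-value is the worse (max) of the two directions — both cohorts must agree.
Bonferroni and Benjamini-Hochberg adjustments over all pairs are returned.
This is a reconstruction of the subclass-mapping idea validated by
self-consistency (self-mapping puts the minima on the diagonal; matched
planted subtypes are significant across independently generated cohorts;
permuted labels are null-calibrated), not by reproduction of any published
association matrix.

## Copy-number and alteration statistics

FGA treats segment means as log₂(copy number / 2) and counts the bases in
segments with |log₂R| strictly greater than 0.2 over all profiled bases;
coordinates are 1-based inclusive, unprofiled genome never enters the
denominator, and overlapping segments within a sample are an error because
base counting would be ambiguous.  FGA is invariant to splitting a segment
into adjacent pieces with the same ratio.  Alteration co-occurrence uses
one-sided Fisher exact tests on the 2×2 presence table, testing the
"greater" tail for co-occurrence and the "less" tail for exclusivity and
reporting the stronger direction with tiers at p < 0.1 / 0.05 / 0.01.
Constant events are skipped with a warning.  Because the reported p is the
better of two one-sided tails, its null rate is bounded by twice the
nominal level; the calibration test checks exactly that bound.

## Overlap and differential-expression statistics

The representation factor is k/(mn/N) with an exact hypergeometric upper
tail p = P(X ≥ k); a continuity-corrected normal approximation is used only
for universes above 10⁶ genes (genome-scale universes always get the exact
tail), and the method used is recorded on the result.  RF is reported to
one decimal, following the field's presentation convention.

Differential expression here is a deliberate stand-in for count-model DE:
log₂ fold change as the difference of group means on the log₂ scale, an
exact two-sided Mann-Whitney p per gene, and BH FDR.  It requires no raw
counts and is exact at the small group sizes where the downstream
contingency claims live, but its gene lists are not expected to match a
negative-binomial GLM's gene-for-gene; published DE gene counts are
therefore not reproduction targets.  The threshold filter is strict on all
three criteria (FC > 2 or < 0.5, p < 0.05, FDR < 0.25): a gene exactly at
a boundary is excluded.

Pre-ranked GSEA uses the classic weighted Kolmogorov-Smirnov running sum
(weight 1 by default), the ES being the signed maximal deviation.  The null
permutes gene labels — on a pre-ranked list a sample-level phenotype
permutation is not available — drawing random same-size sets; NES divides
the ES by the mean |null ES| of the same sign, the nominal p is the
same-sign permutation tail with the +1 correction, and FDR is BH over the
sets' nominal p-values.

## Drug-sensitivity inference

Missing training log-IC50 entries are filled by k-NN imputation (k = 5):
Euclidean distance on per-drug z-scored profiles restricted to jointly
observed drugs, scaled by the number of common drugs, and the mean of the
k nearest observed lines on the original scale.  Ridge prediction
intersects genes between training and test, drops training genes with
sd < 10⁻⁸, standardizes both matrices with the training statistics, picks
the penalty minimizing mean 10-fold CV squared error over 25 log-spaced
points in [10⁻³, 10³], and refits on the full training set; the penalty is
tuned per drug.  Training and prediction are on the log-IC50 scale (an
exponentiation helper is provided).  Group contrasts use a one-sided Welch
t-test with the direction fixed by the caller; identical constant groups
make the test undefined and are flagged (NaN), not silently resolved.

The 4PL model r(d) = lower + (upper−lower)/(1+(d/ic50)^hill) is fitted by
least squares with multi-starts over the hill-slope sign and magnitude;
the fitted curve passes through (lower+upper)/2 at d = ic50 by
construction.  The convergence flag requires the curve to explain at least
half of the response variance (R² ≥ 0.5): trendless data yields an explicit
non-convergence, never a silent parameter set.  The combination index is
D₁/Dx₁ + D₂/Dx₂, with "additivity" called only at |CI − 1| ≤ 10⁻⁹.

## Survival

Kaplan-Meier estimation and the log-rank test are delegated to standard
survival tooling; the maximally selected rank statistic is an exhaustive
scan over candidate cutpoints (observed marker values, `marker > cut`
defining "high") that leave at least `min_prop` (default 0.1) of subjects
on each side, computing the standardized log-rank statistic
(O−E)/√V per split and returning the maximizing cutpoint, ties resolved to
the smaller value.  The naive p at the selected cutpoint is
anti-conservative — the cutpoint was chosen to maximize the statistic — so
it is labelled as such, and an optional permutation-adjusted p (marker
shuffled, full scan repeated) quantifies the selection effect.

## Regulons

Mutual information uses equal-frequency binning into ⌈√n⌉ bins per gene — a
simple, fully deterministic estimator chosen over adaptive alternatives.
Candidate edges (regulator × every other gene) are signed by Spearman
correlation, filtered by a per-regulator sample-permutation null with BH
FDR across all edges (the null depends only on the bin margins, so one
permuted partner per regulator suffices), then subjected to bootstrap
consensus: an edge is "recovered" in a resample if its MI exceeds the 95th
percentile of the regulator's permutation null, and must be recovered in
more than `consensus_min` (default 0.95) of resamples.  DPI pruning removes
the weakest edge of every regulator–regulator–target triangle unless it is
within `dpi_tolerance` (default 0, strict) of the second weakest.  Regulon
activity ranks each sample's genes by expression centered on the gene's
cohort mean and uses centered ranks as the running-sum scores, keeping the
statistic purely rank-based (adding a constant to a sample's expression
vector changes nothing); activity is ES(positive targets) − ES(negative
targets).

## Synthetic cohorts

The generator plants exactly the structure the analysis assumes, at the
scale of an anaplastic WT cohort: 60 samples, 2000 genes, a 24-cell-type
compendium of 15 genes each (~360 signature genes, mirroring a 364-gene
compendium), one third of samples desert-like.  Expression is drawn on the
log₂ scale (gene baselines Uniform(2,8), Gaussian noise sd 0.5),
back-transformed and column-normalized to TPM.  Infiltrated samples have
signature genes elevated by `infiltration_effect` (default 2 log₂ units)
times a per-cell-type multiplier drawn once per cohort from
Uniform(0.5, 1.5): real microenvironments do not elevate all cell types
equally, and this heterogeneity is what gives correlation-based clustering
a profile *pattern* to work with — under a perfectly uniform elevation the
phenotype signal lives entirely in score magnitude, which the
1 − Pearson distance deliberately ignores.  Purity is Beta(8, 2)
(right-skewed, as in real tumor cohorts) and independent of phenotype.
Copy-number segments are equal-length tiles whose altered fraction tracks a
per-phenotype mean FGA (5 % infiltrated, 20 % desert); altered tiles draw
|log₂R| from Uniform(0.3, 1), unaltered from a truncated normal inside the
±0.2 boundary.  A TP53-like binary event occurs in desert samples with
sensitivity 0.8 and specificity 1.0 (mirroring a 4-of-5 vs 0-of-5 split),
alongside a few independent noise events.  Survival is exponential with a
60-month baseline median and a 3× desert hazard, with independent censoring
at rate 0.3 (censoring times uniform on (0, T)).  Each data domain draws
from its own RNG stream (NumPy PCG64 via SeedSequence spawning), so
changing one block of parameters never reshuffles another domain's draws.

Cell-line training data are 200 lines × genes with log-IC50 linear in
expression (10 causal genes per drug, coefficients N(0,1), noise sd 0.3)
plus optional missingness that never blanks an entire drug or line.  The
held-out validation of the ridge pipeline runs at 100 genes for 200 lines:
expression-based IC50 predictors operate after feature filtering, in the
n > p regime, and the planted-model check mirrors that.

**What passing these tests shows — and does not.**  The synthetic cohorts
validate that each statistic recovers the structure it is designed to
detect, at realistic effect sizes, and that the pipeline's plumbing (seeds,
scales, alignments) is correct.  They do not establish that real WT cohorts
separate into two phenotypes, nor the published cohort-level effect sizes:
the generator has no batch structure, no count-level noise, no correlated
gene modules beyond the planted signatures, and purity independent of
phenotype.  Claims about real data remain with the original study.

## Problem sizes in the test suite

The default test run scales simulations to desk size as the package's own
choice of test conditions: consensus clustering at 100 perturbations (the
production default is 500), 5–20 seeds per replicated check, null
calibrations at 60–200 replicates on reduced cohorts, and regulon
inference on 3-gene chains with 40–100 bootstrap resamples.  Every
stochastic test fixes its seeds.
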