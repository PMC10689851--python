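# wtme — Wilms-tumor microenvironment phenotyping

Bulk transcriptomes of pediatric kidney tumors (Wilms tumor, WT) can be
stratified by the state of their tumor microenvironment (TME): some tumors
are broadly infiltrated by immune and stromal cells, others are almost
devoid of them.  `wtme` implements, end to end, the computational workflow
that discovers these **infiltrated-like (iWT)** and **desert-like (dWT)**
phenotypes and characterizes their genomic, pharmacologic and prognostic
correlates:

1. **Signature scoring.** Single-sample gene-set enrichment (ssGSEA) over a
   compendium of 24 microenvironment cell-type signatures.  For a gene set
   *S* in a sample whose *N* genes are ranked by descending expression,

   `ES = Σᵢ [ P_in^w(i) − P_out(i) ]`,  with in-set weights `(N−i+1)^α`,

   i.e. the area between the weighted cumulative in-set curve and the
   unweighted out-of-set curve.  Scores are adjusted for tumor purity as
   `ES / (1 − purity)`, and samples with purity > 0.98 are excluded.
2. **Consensus subtyping.** 500 perturbations drawing 90 % of features and
   samples, hierarchical clustering with 1 − Pearson distance and Ward
   linkage, consensus matrix from co-clustering frequencies, final cut at
   *k* = 2; the cluster with lower overall cell-type enrichment is dWT.
3. **Genomics.** Fraction of genome altered, `FGA = B_r / B`, the profiled
   bases in segments with |log₂(copy number / 2)| > 0.2 over all profiled
   bases; pairwise co-occurrence / mutual exclusivity of binary lesions by
   one-sided Fisher exact tests.
4. **Overlap statistics.** Representation factor of two gene sets of sizes
   *m*, *n* overlapping in *k* genes out of a universe of *N*:
   `RF = k / (mn/N)`, with an exact hypergeometric tail p-value.  Also:
   a rank-based differential-expression statistic with the strict
   `FC > 2, p < 0.05, FDR < 0.25` filter, BH adjustment, and pre-ranked
   GSEA with a gene-label permutation null.
5. **Pharmacology.** Expression-based log-IC50 prediction by ridge
   regression (penalty tuned by 10-fold CV; missing training IC50s filled
   by k-NN imputation), four-parameter-logistic dose-response fitting, and
   the combination index `CI = D₁/Dx₁ + D₂/Dx₂` (< 1 synergism,
   = 1 additivity, > 1 antagonism).
6. **Survival.** Kaplan-Meier curves, log-rank tests, and marker
   dichotomization by maximally selected rank statistics.
7. **Regulons.** Mutual-information networks around candidate regulators
   with permutation FDR filtering, bootstrap consensus (> 95 % of 1000
   resamples) and data-processing-inequality pruning; per-sample regulon
   activity as a two-tailed rank enrichment of signed targets.

The deposited patient cohorts are controlled-access, so the package ships a
first-class synthetic-cohort generator (`wtme.synthetic`) that plants the
statistical structure the analysis assumes — two latent TME phenotypes,
purity, phenotype-linked copy-number burden and survival hazard, a linear
expression→IC50 pharmacogenomic model and 4PL dose-response curves — making
every stage testable offline.

## Worked example

```python
from wtme import io
from wtme.enrichment import adjust_for_purity, ssgsea_score
from wtme.subtyping import ConsensusParams, consensus_cluster, name_phenotypes
from wtme.survival import logrank_test
from wtme.stats import representation_factor
from wtme.synthetic import CohortSpec, generate_cohort

cohort = generate_cohort(CohortSpec(n_samples=60, seed=1))
logm = io.log_transform(cohort.expression)
profile = adjust_for_purity(ssgsea_score(logm, cohort.compendium), cohort.purity)
subtypes = name_phenotypes(
    consensus_cluster(profile.scores, ConsensusParams(k=2, n_perturbations=100, seed=1)),
    profile,
)
print(subtypes.phenotypes.value_counts().to_dict())

surv = cohort.survival.assign(group=subtypes.phenotypes.loc[cohort.survival["sample"]].to_numpy())
res = logrank_test(surv)
print(f"log-rank chi2 = {res.statistic:.2f}, p = {res.p:.2e}")

print(representation_factor(m=2286, n=1582, k=737, N=16475))
```

Output:

```
{'iWT': 40, 'dWT': 20}
log-rank chi2 = 8.31, p = 3.93e-03
RF = 3.4 (k=737, expected=219.5, P=6.01e-250, exact)
```

The 60-sample synthetic cohort splits into 40 infiltrated-like and 20
desert-like tumors (matching the planted third of desert samples); the
log-rank test detects the planted threefold hazard of the desert phenotype;
and the representation factor reproduces the 3.4-fold enrichment of the
737-gene overlap between two independently derived up-regulated gene lists
against a 16,475-gene expressed universe.

A full pipeline run (simulate → score → subtype → genomics → statistics →
survival → drug-sensitivity) is one call:

```bash
wtme run --config pipeline.yaml     # or: python -m wtme.cli run --config ...
```

which writes per-stage TSV outputs and a machine-readable `report.json`.

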