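# Methods

This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate, and
the numerical conventions that make results reproducible.

## Single-sample enrichment and the FPI

The per-sample score is the integrated rank-weighted ECDF difference.
Within each sample, genes are ranked by expression with average ranks on
ties (`r_i ∈ [1, N]`); for a set *S* of size *k* the score walks the gene
list in decreasing expression order and accumulates

    ES(S) = Σ_{i=1..N} [ P_in^w(i) − P_out(i) ],
    P_in^w(i) = Σ_{j≤i, j∈S} r_j^τ / Σ_{j∈S} r_j^τ,
    P_out(i) = |{j ≤ i, j ∉ S}| / (N − k).

* **τ = 0.25** by default — the de-facto single-sample weighting constant.
* Ordering among tied expression values is made deterministic by a stable
  sort on (−rank, gene position); tied genes carry equal weights, so the
  residual ambiguity only permutes equal contributions.
* The score depends on expression only through within-sample ranks, so it
  is invariant to any per-sample monotone transform; a constant-expression
  sample has no ranking and is rejected.
* Sets with fewer than 2 genes mapped onto the matrix are skipped with a
  warning; genes in a set but absent from the matrix are dropped and
  counted, never an error.
* `normalize=True` divides the whole set-by-sample table by its global
  range (max − min of raw scores). This preserves orderings within and
  across samples and makes pathway and regulator scores commensurable.
  The range-normalized single-sample score is used uniformly, including
  where a kernel-density GSVA estimator could also have been used: one
  estimator keeps the FPI and the pathway scores on the same scale. This
  is a deliberate simplification and is the package's documented choice.

The ferroptosis potential index is `FPI = ES(positive) − ES(negative)`
over the 16-gene regulator panel (12 drivers, 4 suppressors). The source
lists describe the panel as "24 regulator genes" but enumerate only 16;
the 16 enumerated genes are shipped as the default panel rather than
inventing the missing eight. FPI inherits rank invariance and is exactly
antisymmetric under swapping the two panel sides.

High/low stratification: the default is the median split (deterministic;
scores strictly above the median are "high", ties go "low"). A maxstat
split is available — the cutpoint maximizing the two-group log-rank
statistic subject to each stratum holding ≥ 10% of samples — because
optimal-cutpoint stratification is common in survival tooling and the
choice between the two is not dictated by the analysis itself.

## Pre-ranked GSEA

For a gene ranking (e.g. DE log2 fold changes), the enrichment score is
the signed maximum deviation from zero of the weighted running sum (hits
increment by |score| normalized over in-set genes, misses decrement by
1/(N−k)). The null is **gene-label permutation**: membership is
re-assigned to random k-subsets of the ranked genes. NES divides ES by
the mean |permuted ES| of matching sign; the nominal p is the
matching-sign tail `(1 + #{|ES_perm| ≥ |ES|}) / (1 + #same-sign)`, so
p ∈ (0, 1]; BH adjustment is applied across sets. Phenotype permutation
is not offered — a pre-ranked input carries no phenotype labels to
permute. At `n_perm = 1000` the nominal p is calibrated (type-I error
0.05 ± 0.02 over 500 null sets in the test suite).

## Immunophenoscore

Per gene, z-scores across the cohort (sample SD, ddof = 1; zero-variance
genes get z = 0 with a warning). A component score is the mean over its
member rows of `weight × z`; a category score (MHC, CP, EC, SC) is the
unweighted mean of its component scores; AZ is the mean of the four
category scores ("sum" is offered as a flag — it is a monotone rescaling).
IPS maps AZ linearly to integers 0–10: 0 at AZ ≤ 0, 10 at AZ ≥ 3, half-up
rounding between (half-up rather than banker's so the mapping is monotone
and independent of parity). The mapping follows the published
immunophenogram convention. The gene/weight table itself belongs to that
publication and is therefore a user-supplied input; the package ships a
small clearly-synthetic table (`synthetic_ips_table`) for tests and
demonstrations. `IPSScorer.fit` stores the cohort means/SDs so new
samples can be scored against a frozen reference cohort.

## Differential expression

Size factors are DESeq-style median-of-ratios: for genes with nonzero
counts in every sample, the per-sample median of count / geometric mean.
Note the equivariance caveat: multiplying one library by *c* scales its
factor *relative to the others* by exactly *c*; the absolute factors
absorb `c^{1/n}` through the geometric means. An optional rescaling
divides factors by their own geometric mean.

The two-group test is a Wilcoxon rank-sum on normalized counts with the
tie-corrected normal approximation (no continuity correction, so
identical groups give p = 1 exactly). This replaces a negative-binomial
Wald test deliberately: it is deterministic, assumption-light, and the
decision gates of the analysis — |log2FC| ≥ 1.0 and BH-adjusted p < 0.05 —
are preserved unchanged. Fold changes are `log2((mean_A+1)/(mean_B+1))`
on normalized counts (pseudocount 1 bounds the fold change at zero
counts). Genes with mean normalized count below 1 across all samples are
removed before testing; the published analysis filtered "low-expression
genes" without stating its cut-off, so the threshold is explicit here and
recorded in the result object. Multi-group comparisons use one-way ANOVA
with pairwise t-tests multiplied by the number of pairs (Bonferroni).

## Single-cell QC and markers

Cells are filtered first: detected genes per cell within [200, 20,000]
(the stated "minimum number of features = 200" coincides with the range's
lower bound and is treated as the same rule) and mitochondrial count
fraction strictly below 0.05 (gene IDs matching the `^MT-` pattern by
default). Genes detected in fewer than 3 remaining cells are then
removed. The report counts each rule independently and the removed union,
since a cell can fail several rules. Filtering cells before genes makes
the operation order-stable; it is idempotent on realistic data (gene
removal can in principle drop a borderline cell below the feature
threshold on a second pass, which the planted fixtures avoid by
construction and real data rarely exhibits).

Markers are one-vs-rest per cluster: detection fraction in-cluster
(`min_pct = 0.25` on the in-cluster fraction), `log2((mean_in+1)/
(mean_out+1)) ≥ 0.25` (positive markers), Wilcoxon rank-sum on
log2(count+1) with BH adjustment within cluster (< 0.05). Clusters with
fewer than 3 cells are skipped with a warning.

## Survival analysis

Kaplan–Meier, the two-group log-rank test and the Cox fit are delegated
to lifelines; the package adds the Greenwood variance
`S(t)² Σ d_i/(n_i(n_i−d_i))` from the event table, Wald CIs
`exp(β ± 1.96·SE)`, and a direct implementation of the partial-likelihood
**score test at β = 0** (`U²/I` over risk sets), which is not exposed by
the fitters and which coincides with the log-rank χ² for a binary
covariate without tied event times — a cross-check the test suite
exercises to 1e-8. Efron tie handling is the default (synthetic integer
times produce ties); Breslow is available by flag. Endpoint labels
(OS/PFI/DSS) are carried as metadata only.

## Synthetic data

* **Counts**: gene base means log-uniform on [5, 500] (spanning low- to
  high-expressed genes at bulk RNA-seq depth); negative binomial with
  size (inverse dispersion) 10, i.e. var = m + m²/10, a typical bulk
  overdispersion. Planted DE multiplies group means by `2^log2FC`;
  planted set activity multiplies member means by the effect size in
  active samples. Factors may be crossed (the pipeline plants a
  tumor/normal and a progression-stage factor).
* **QC cells**: normal cells detect ~600 of 1,000 genes with a
  mitochondrial fraction near 0.01; planted violators get a fraction of
  0.2 or a detected-gene count of 150 — wide margins on both sides of the
  thresholds, so the planted labels are the unambiguous ground truth.
* **Survival**: event times from `Exponential(λ0·e^{β·score})`; censoring
  from an independent exponential whose rate is solved by bisection so
  the expected censored fraction matches the request (keeping censoring
  non-informative). `censor_rate = 0` disables censoring.
* Every generator is a pure function of its config (seed included), and
  ground truth serializes to JSON alongside the fixtures.

What the generators do **not** emulate: Smart-Seq2 technical artifacts
(dropout curves, gene-length bias), batch effects, correlated gene-gene
structure beyond the planted blocks, or non-proportional hazards. Passing
recovery tests therefore demonstrates correctness of the statistics under
their own model assumptions, not robustness to real-data pathologies.

## Pipeline and problem sizes

The end-to-end synthetic run uses 2,000 genes × 100 samples, 60+60
planted DE genes per factor at log2FC 3, 4 hub genes planted in both
factors and the ferroptosis set, positive regulators boosted ×4 in tumor
samples, and survival simulated from the standardized FPI with β = 0.5
per SD, λ0 = 0.1, 30% censoring — sizes at which every stage's planted
structure is comfortably recoverable and a full run takes a couple of
seconds. One global seed fans out to per-stage seeds by fixed offsets so
toggling stages does not shift the streams of the others. Outputs are
plain text with fixed float formatting (`%.10g`), making reruns
byte-identical; the manifest records parameters and SHA-256 digests
(its stage timers are the only non-reproducible fields).

## Numerical conventions and edge cases

* Gene ID matching is exact and case-sensitive (an uppercase-fold flag
  exists where sets map onto matrices): silent case-folding hides mapping
  bugs.
* Wilcoxon tests use the tie-corrected normal approximation without
  continuity correction; all-tied comparisons report p = 1.
* BH adjustment is the step-up procedure with monotonicity enforcement,
  clipped at 1 (delegated to statsmodels, verified against a brute-force
  implementation).
* Spearman correlations of constant columns are undefined: flagged NaN
  and excluded from the 1−ρ average-linkage clustering; the dendrogram
  exports as Newick.
* Degenerate inputs fail loudly: empty matrices after QC, all-identical
  scores at a split, constant covariates in Cox, zero-information score
  tests, p-values outside [0, 1].

## Known limitations

* The DE module's rank-sum test has less power than NB likelihood tests
  at very small n and does not model dispersion shrinkage.
* Only univariate Cox is provided; no proportionality diagnostics.
* The single-sample scorer loops over samples; very large cell matrices
  (10⁵+ cells) would need a blocked implementation.
* The IPS weights shipped are synthetic; scientific use requires the
  published immunophenogram table.
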