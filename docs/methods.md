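# Methods

This note documents the models implemented in `metaquad`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a user auditing results will want to
know. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Batch correction (`metaquad.batch_correct`)

Parametric empirical-Bayes location/scale adjustment (the ComBat model).
For gene *g*, sample *j* in batch *b*:

    x_gbj = alpha_g + gamma_bg + delta_bg * eps_gbj,   eps ~ N(0, sigma_g^2)

Each gene is standardized by its grand mean (batch-size-weighted) and pooled
residual variance; per-batch locations `gamma_bg` and scales `delta_bg^2`
are estimated on the standardized data and shrunk with conjugate priors —
normal on locations, inverse-gamma on scales, hyper-parameters by method of
moments per batch — through the standard iterative joint update
(tolerance 1e-6, max 500 iterations; `ConvergenceError` past the budget).
No covariate design, mean **and** scale adjustment: the published defaults.
Genes with zero pooled variance pass through uncorrected with a warning;
batches with a single sample are rejected with advice to exclude them.

Two facts about EB shrinkage worth knowing (both verified against the
reference `sva::ComBat` behavior and asserted in the tests at their true
magnitude):

- **Residual batch differences scale with the batch effect's gene-level
  heterogeneity.** For a *gene-constant* shift, the prior variance `tau^2`
  is pure sampling noise, shrinkage is strong, and per-gene between-batch
  differences of order `1/sqrt(n_b)` remain (≈0.1 log2 units at
  100/batch). For realistic per-gene batch effects (`gamma_bg` spread ≈ 1)
  shrinkage is weak and residuals drop an order of magnitude.
- **The correction is not exactly idempotent**: a second pass re-shrinks
  the EB residuals, moving entries by a few percent (RMS) of the first
  pass. It is a strong contraction, not a projection.

`pca_batch_check` computes top-2 PC scores on gene-centered data and the
mean silhouette of batch labels in the PC1-2 plane before and after
correction. Well-mixed batches give silhouettes near or below zero.

## Consensus clustering (`metaquad.consensus_cluster`)

Genes (rows of the Z-scored matrix) are items; samples are features.
Defaults mirror the reference resampling scheme: 1000 reps, `p_item` = 0.8,
`p_feature` = 1.0, agglomerative hierarchical clustering with euclidean
distance and **average linkage** for both the per-rep clustering and the
final clustering of `1 - M` (the reference implementation's default; only
"hierarchical" is prescribed). Consensus `M_k[i,j]` divides co-clustering
counts by *co-sampling* counts — the unbiased denominator under item
subsampling; a pair never co-sampled is an error instructing more reps.
Per rep the linkage is computed once and cut at every k, so all k share one
subsample stream and the whole result is bit-reproducible given the seed.

Cluster-count selection: `A(k)` is the exact area under the empirical step
CDF of the upper-triangle consensus values over [0, 1] (for a step CDF
this equals `1 - mean(M)`, an identity the property tests exploit).
The relative delta-area is `A(2)` at k=2 and `(A(k)-A(k-1))/A(k-1)` beyond;
the chosen k is the largest one whose relative gain exceeds the threshold
(default 0.05), unless the user fixes k (the pipeline default fixes k = 10,
the cluster count the quadrant analysis is defined on).

Module selection labels each cluster by the pathway of the majority of its
members and, per pathway, takes the cluster with the highest mean
intra-cluster consensus among clusters with ≥ 3 members. Because consensus
saturates — every stable block co-clusters in essentially every rep —
clusters within 0.05 of the pathway's best are treated as equally robust,
and the tie breaks by **mean within-cluster pairwise correlation** (the
most strongly co-expressed cluster wins), falling back to cluster size when
no expression matrix is supplied. The 0.05 band matches the delta-area
threshold convention; gaps larger than resampling noise still decide on
consensus alone.

## Quadrant subtyping (`metaquad.metabolic_subtype`)

Scores are medians of gene-wise Z-scores (one standardization pass over the
merged, batch-corrected cohort — quadrant boundaries at zero only make
sense post-standardization; medians are computed on the merged matrix, as
correction precedes subtyping). Even-sized modules use the mean of the two
central order statistics. The four labels partition the score plane with
inclusive zero boundaries (a score of exactly 0 goes to the "low" side);
non-finite scores are rejected. Proportions are reported in percent to one
decimal.

## ssGSEA and screens (`metaquad.signature_scores`)

ssGSEA follows the single-sample rank-weighted running-sum form: per
sample, genes get average ranks; walking from highest to lowest expression,
the running sum gains `rank^alpha / sum(rank^alpha over the set)` at member
genes and loses `1/(N - |S|)` elsewhere; the enrichment score is the sum of
the running-sum deviation over all N positions (the integral form), making
it invariant under any strictly monotone transform of a sample's values.
`alpha` defaults to 0.75 per the original description. With
`normalize=true`, all scores are divided by the global (max − min) of the
score matrix for cross-sample comparability. The stemness index is an
*input* clinical covariate, never computed here.

The correlation screen computes product-moment r of every gene against each
anchor (default PDK1-3) with two-sided P from
`t = r sqrt((n-2)/(1-r^2))`; significance defaults to |r| > 0.3 and
P < 0.001; anchors are excluded from their own results and the intersection
across anchors is reported. Over-representation is the upper-tail
hypergeometric P of the query/set overlap within a user-chosen universe
(default: all genes in the expression matrix, since enrichment backgrounds
are analysis-specific), BH-adjusted across sets.

## Immune deconvolution (`metaquad.immune_deconv`)

Per bulk sample, restricted to genes shared with the signature (≥ 10
required): mixture and signature are each standardized by their global
mean/sd (this also makes the estimate exactly invariant to positive global
scaling of the mixture); a linear-kernel nu-SVR is fitted for
nu ∈ {0.25, 0.5, 0.75} (solver tolerance 1e-6 for reproducibility) and the
nu minimizing reconstruction RMSE wins; negative coefficients are clipped
to zero and the rest normalized to fractions summing to 1 (all-nonpositive
coefficients yield uniform fractions with a flag). The permutation P is the
fraction of `n_perm` gene-label permutations of the sample whose
reconstruction correlation reaches the observed one, refitted at the
selected nu. Quantile normalization of microarray inputs is deliberately
omitted — inputs are assumed comparably normalized — and no reference
signature is redistributed; any marker × cell-type TSV works.

## Survival and contingency statistics (`metaquad.cohort_stats`)

Kaplan-Meier, the k-group log-rank test and Cox proportional-hazards fits
are delegated to lifelines; Cox uses Efron tie handling (less biased than
Breslow under the heavy ties of monthly follow-up). Subtypes are
dummy-coded against the quiescent reference, other categoricals against
their first sorted level; rows missing any covariate are list-wise deleted
with a logged count (the generalization of excluding a cohort that lacks
stage/grade). Coefficients diverging past |beta| = 20, or a Newton step
still large at termination, raise a `ConvergenceError` advising exact or
penalized handling. Note that Efron's correction is *not* exactly
replication-invariant: duplicating every record shifts the estimate
slightly (Breslow's does not), which the tests verify numerically.

Fisher's exact test for r × c tables is authored here: exact
(Freeman-Halton) by full enumeration of margin-compatible tables when the
total is ≤ 200, two-sided by summing probabilities no larger than the
observed table's (with the customary 1e-7 relative slack against float
round-off); beyond that, Monte Carlo with 1e5 draws from the
margin-conditioned null at a fixed seed (vectorized via the multivariate
hypergeometric for r × 2 tables). Alteration-frequency families
(subtype × altered/not per gene, modes: any alteration, CNV loss, CNV
gain, SNV) are BH-adjusted across genes. The generic association test uses
the r × c chi-square without continuity correction and switches to the
exact machinery whenever an expected count falls below 5.

## Synthetic cohorts (`metaquad.synthetic_cohort`)

The generator emulates a merged three-cohort study of 400/165/195 samples
(760 total) and 2,097 genes: 2,000 background genes (including named
pyruvate-fate regulators and 60 immune marker genes), a planted 12-gene
glycolytic and 8-gene cholesterogenic module, and 60 + 17 decoy pathway
genes so the clustering stage faces the realistic 72 → 12 and 25 → 8
reduction. Expression follows

    X[g,s] = mu_g + lambda*a_g(s)*1[g in M_g] + lambda*a_c(s)*1[g in M_c]
           + (S f_s)[g]*1[g marker] + gamma_b(s),g + delta_b(s)*eps

with mu_g ~ N(7, 2^2) (a typical log2 abundance range), lambda = 1,
eps ~ N(0, 1).

- **Latent activities.** Subtype labels are multinomial with prior
  (0.311, 0.222, 0.225, 0.243) for (quiescent, glycolytic,
  cholesterogenic, mixed) — the observed subtype mix, used as a generator
  parameter. Given the label, (a_g, a_c) is a 2-D Gaussian with mean
  ±2.0 per axis and sd 1.0, rejection-truncated to the quadrant's signs,
  so the median-sign rule is the Bayes rule by construction and
  misassignment occurs only near the axes. The ±2.0 separation was chosen
  once as a clearly-but-not-perfectly separated regime (~3-4% per-axis
  overlap at sigma = 1).
- **Decoy blocks.** Decoys are *uncorrelated with the modules and the
  subtype* but co-express in their own blocks (5 glycolysis, 3 cholesterol
  blocks; shared N(0,1) factor, loading 0.5), as real pathway genes do.
  This matters: fully independent decoys form no stable clusters, the
  k = 10 cut then has no meaningful structure, and no consensus method can
  recover the modules as exact sets. With block decoys the gene dendrogram
  has 10 genuine blocks — 2 strong modules and 8 weaker decoy blocks — and
  the pipeline recovers the modules exactly.
- **Batch effects** follow the ComBat family the correction assumes:
  per-gene additive effects `gamma_bg ~ N(shift_b, 1)` with cohort shifts
  (0, +1.5, −1.0) and multiplicative noise scales (1.0, 1.3, 0.8) — the
  per-gene sd of 1 reflects cross-platform (array vs RNA-seq) merges where
  gene-level probe and mapping differences dominate.
- **Survival** is exponential proportional hazards: baseline 0.02
  events/month (median ≈ 35 months for quiescent) with log hazard ratios
  (0, ln 1.5, ln 1.2, ln 2.0) and uniform(6, 120)-month administrative
  censoring. The mixed-vs-quiescent HR of 2.0 is the planted effect the
  Cox stage must recover.
- **Copy number.** RB1 and LRP1B loss probabilities are subtype-specific
  generator parameters — 25.7% (mixed) vs 12.7% (quiescent) and 27.9% vs
  10.2%, intermediate subtypes at 19% — with gains more common than losses
  for module genes (15% vs 5%) and rare SNVs (2%), matching the observed
  pattern that deletions in these two tumor suppressors, not point
  mutations, distinguish the aggressive subtype.
- **Immune mixtures.** A block-structured marker signature (5 cell types ×
  60 markers) with Dirichlet(1) fractions; the mixture term is added on the
  log-expression scale, which is a simplification (real deconvolution
  operates on linear-scale mixing).
- **Clinical covariates** (age, gender, grade, stage, molecular phenotype,
  stemness index, trial-cohort-only immunotherapy response) carry mild
  subtype links so adjusted models and association tests have realistic
  structure; response is independent of subtype by design (the null the
  original comparison could not reject).

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: read-count noise (expression is Gaussian on
the log scale), probe-level microarray artifacts, linear-scale immune
mixing, correlated mutation processes or signatures, non-proportional
hazards, and informative censoring. Tests on these cohorts demonstrate the
pipeline's correctness and calibration, not the biological validity of any
particular stratification.

## Reproducibility and problem sizes

Every random draw descends from a single run seed through named,
hash-derived per-stage substreams (`derive_seed(seed, stage)`,
blake2s-based, < 2^31), so adding or disabling a stage never shifts another
stage's stream and stage-level reruns reproduce in isolation. The test
suite and the acceptance script run the clustering stage at 200 resampling
reps rather than the 1000 default, a size at which module recovery is
already at ceiling across 100 seeded replicate cohorts; survival
calibration uses 500 null simulations (CI coverage) and 100 replicate
cohorts (hazard-ratio recovery); type-I-error checks use 1000 replicates
per test family; the Fisher implementation is swept exhaustively against an
exact-rational oracle over all 2×2 and 2×3 tables with total ≤ 20.

## Known limitations

- Parametric priors only (no nonparametric-prior ComBat, no reference
  batch); no covariate-preserving correction.
- No k-means/PAM clustering alternatives or feature-weighted distances.
- Hard-threshold subtypes only; no continuous subtype probabilities.
- No GSEA permutation NES/FDR; no GO-DAG-aware term reduction; enrichment
  universes are the user's responsibility.
- No absolute-mode deconvolution scores; no quantile normalization.
- No time-varying covariates, competing risks, or proportionality
  diagnostics beyond convergence checks; separation is detected, not
  handled (no Firth correction).
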