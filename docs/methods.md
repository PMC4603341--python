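# Methods

## Scope and model

`pancimp` implements the standard pan-cancer CIMP methodology as a tested
pipeline. A CIMP is operationalised as the two-way partition of a tumor
cohort obtained by Ward/Euclidean hierarchical clustering of samples on the
most variant CpG islands, with the hypermethylated cluster labeled
CIMP-positive. Everything downstream — cluster-number assessment,
cross-tissue signature intersection, expression-based prediction, mutation
and clinical association — conditions on those calls.

## Methylation aggregation

The beta value β = M/(M+U) is the methylation fraction at a probe; no
offset constant is added to the denominator. Probes are averaged per CGI
(arithmetic mean, the standard 450K region summary), pooling island, shore
(≤2 kb) and shelf (2–4 kb) probes by default; open-sea probes never
contribute. Missing probe values are ignored in the mean. CGIs missing in
more than a configurable fraction of samples (default 0.3) are dropped, and
remaining gaps are imputed with the CGI's per-cohort mean. Annotation
coordinates are stored 1-based (manifest convention) and converted to
0-based half-open only for BED export; strand is ignored because CpG
methylation is symmetric. The CGI universe size is data-driven, never
hard-coded.

## CIMP calling

The signature is the top ⌈fraction·n⌉ CGIs by unbiased (n−1) sample
variance, default fraction 0.05; ties at the cutoff break lexicographically
by CGI id so selection is deterministic. Clustering uses scipy's Ward
linkage on Euclidean distances with a maxclust cut. For k = 2 the labeling
rule — higher mean signature methylation ⇒ CIMP-positive — is asserted on
every call; for k > 2 clusters are numbered 1..k by increasing mean
methylation. Signatures are always computed per tissue cohort; tissues are
pooled only for the cross-cancer re-clustering step, which restricts to the
already-computed common CGI set.

## Consensus clustering and Δ(K)

For each K in 2..5 (configurable), samples are subsampled without
replacement (default 100 resamples of 80 %; no feature subsampling) and
re-clustered; consensus(i,j) is the fraction of co-subsampled runs in which
i and j co-clustered, undefined (and excluded) for pairs never co-sampled.
A(K) is the area under the empirical CDF of the off-diagonal consensus
entries, computed as the exact step-function integral A = 1 − mean(entries);
a 101-point grid CDF is stored for plotting. The exact integral (rather
than a grid trapezoid) is used so that on noiseless block-structured data
A(K) equals its combinatorial closed form to machine precision. The
cluster-number score is Δ(2) = A(2) and Δ(K) = (A(K) − A(K−1))/A(K−1) for
K ≥ 3; its argmax (ties toward smaller K) is the suggested cluster number.

A caveat this package's tests surfaced: with the Δ(2) = A(2) convention,
three *pairwise-equidistant* equal-sized clusters are a boundary case — the
ideal-limit margin Δ(3) − Δ(2) is only ≈ 0.06 and is easily erased by
consensus-estimation bias. The bundled three-class generator therefore
plants an intermediate-methylation ladder (widening gaps toward the top,
mildly decreasing cluster sizes), the structure actually hypothesised for a
third CIMP class, for which the ideal values are Δ(2) ≈ 0.38 and
Δ(3) ≈ 0.74.

## Cross-cancer signature

Per-tissue signatures are intersected exactly (plus pairwise counts). The
analytic null for T independent uniform p-subsets of N CGIs is an expected
overlap of N·p^T; a Monte-Carlo routine re-estimates it by direct
simulation and additionally reports the exceedance probability of a
non-empty overlap (an extension beyond the analytic expectation, clearly
labeled in the report). CGI→gene mapping for reporting takes the union of
annotated gene symbols over the CGI's probes; CGIs with no genes are
reported as unannotated.

## Expression-based prediction

Features are log2(RPKM+1), standardized per gene to zero mean and unit
variance *within tissue* (population variance), constant genes dropped.
Three estimators share one FISTA solver (exact spectral Lipschitz step,
monotone function-value restarts, 5,000-iteration cap, 1e-7 relative
objective tolerance; unpenalized fits at λ = 0 may legitimately stop at the
iteration cap when data are separable):

* **lasso** — mean logistic loss + λ‖w‖₁, single unpenalized intercept;
* **combined lasso** — samples pooled across tissues with one coefficient
  vector and per-tissue unpenalized intercepts (absorbing prevalence
  differences);
* **group lasso** — per-tissue coefficient vectors W·t with penalty
  λ√T Σ_g ‖W_g·‖₂ and per-tissue losses weighted 1/(T·n_t), so the selected
  gene *set* is shared while coefficients differ. √T weighting and
  per-tissue loss normalisation follow the standard multi-task group-lasso
  convention. A gene is selected when its coefficient (group norm) exceeds
  1e-8.

λ_max — the smallest penalty at which all coefficients are exactly zero
with intercepts at the class log-odds — is computed in closed form, and the
grid is 50 log-spaced values down to 0.01·λ_max (both configurable).

**Penalty selection.** Two inner-CV policies are exposed, because one
criterion cannot serve both goals. For *accuracy evaluation* the penalty
minimizes held-out deviance (min rule). For *support recovery and
signatures*, held-out deviance is uninformative under strong signal — it
decreases monotonically along the entire path as margins sharpen, so its
argmin degenerates to the grid floor and selects several times the true
support. Signature fits therefore use held-out *misclassification error*
with the one-standard-error rule, the conventional sparse-selection choice;
with it the group lasso recovers a planted 10-gene shared support with mean
F1 ≈ 0.9 under the default conditions.

Accuracy is estimated by stratified (class × tissue) 3-fold CV repeated 100
times; significance against the majority-class baseline is a one-sample,
one-sided Student t over the repeat means (the baseline is a constant, so
the one-sample form is forced). Bootstrap stability resamples within
tissue with replacement (single-class draws are redrawn, ≤10 attempts) at a
penalty fixed once on the full data; genes at ≥50 % selection frequency
form the signature (a 0.49 frequency is excluded).

## Mutation association

Genes with ≥3 mutated samples (configurable) are tested with two one-sided
hypergeometric tails (enrichment in either CIMP class); p = 2·min(tails)
capped at 1, with the direction reported, then BH-corrected. The
two-sided form is used so depletion as well as enrichment is detectable.
Mutation burden per sample is compared between classes with the two-sided
Wilcoxon rank-sum test (robust to the heavy-tailed counts); fully tied
data return p = 1. A helper collapses a minimal MAF (gene / sample /
variant-classification columns) to a binary matrix, counting any
non-silent variant.

## Survival and clinical association

Kaplan-Meier estimation, the two-group log-rank test, and Cox proportional
hazards regression are delegated to lifelines (Efron tie handling); the
default Cox model is CIMP + age with the covariate list configurable.
Survival times are taken from the clinical table as provided. Numeric
covariates use Welch's t (pooled-variance optional); categorical covariates
use the chi-squared test without continuity correction, flagged when any
expected count is below 1; missing values are dropped per covariate.

## Synthetic-data generator

The generator is the package's study-condition definition; all randomness
flows from one seeded NumPy generator with a documented draw order (planted
sets → annotation layout → per tissue: labels, CGI betas, probe noise,
expression, mutations, clinical, survival).

* **Methylation.** Each background CGI carries one fixed mode — a
  hypomethylated Beta(2,8) or hypermethylated Beta(8,2) distribution
  (hyper-mode weight 0.3) — matching the bimodal but per-region stable
  behaviour of 450K betas. Planted CGIs (default 25 of 500, i.e. the 5 %
  signature size; 60 % shared across tissues) start from the hypomethylated
  mode, and CIMP-positive samples (prevalence 0.3) are shifted additively
  by cimp_shift = 0.35 with clipping to [0,1]; because the base mode is
  low, clipping is rare and the realised CIMP+/− mean difference tracks the
  nominal shift within ±0.05. Probe values add N(0, 0.03) noise, clipped.
  An additive-with-clipping shift is used instead of a constant logit-shift
  because the latter's induced mean difference varies with the base value
  and cannot be held to the nominal effect size.
* **Expression.** Per-gene Gaussian on the log2 scale (baseline means
  N(4, 2), unit within-gene SD), exponentiated to RPKM-like positives.
  Predictive genes (default 20 of 500, shared across tissues) are shifted
  by expression_effect = 1.5 SD in CIMP-positive samples — chosen once to
  emulate the clear class separation the predictive genes show in real
  cohorts.
* **Mutations.** Per-gene Bernoulli(0.01); five planted genes have their
  odds multiplied by 8 in CIMP-positive samples.
* **Survival.** Exponential with ~1000-day baseline median and hazard
  ratio survival_hr for CIMP-positive (default 1: no planted effect);
  censoring times are Uniform(0, c) with c solved numerically so the
  expected censoring fraction matches the configured rate (default 0.3).
* **Clinical.** Age N(63, 10) with an optional CIMP shift; MSI, ER/PR/HER2
  and T/N/M are drawn independently of CIMP by default.

What the generator does *not* emulate: array chemistry artifacts (dye bias,
probe type I/II differences, detection p-values), tumor purity and copy
number, correlated gene networks, and tissue-specific mutational
signatures. Passing tests therefore demonstrate correctness of the
algorithms under a clean planted-signal model, not robustness to every
real-data nuisance.

## Problem sizes and numerical choices

The package defaults mirror the analysis constants (5 % signature, K = 2..5,
100 consensus resamples at 80 %, 100×3-fold CV, 100 bootstraps, 50 %
signature threshold, BH α = 0.05, CGI missingness 0.3). The test and
acceptance suites run the simulation studies at the sizes stated in their
docstrings — e.g. 20 seeds × 3 tissues × 200 samples for label recovery,
10 seeds for cluster-number and support-recovery experiments, 1,000 null
replicates for test calibration — and reduced CV repeats/λ-grids for the
CV machinery checks; these are the package's chosen experiment sizes, and
the code accepts larger values unchanged. Degenerate inputs are defined
errors: single-sample variance, k larger than the cohort, a cohort with no
methylation variation, empty cross-cancer signatures, single-class survival
comparisons. Ties in signature selection break lexicographically; fully
tied burden comparisons return p = 1; consensus pairs never co-sampled are
excluded rather than imputed.

## Known limitations

* The group-lasso objective follows the standard multi-task convention;
  other weightings (e.g. per-group √(group size) with unequal group sizes)
  are not implemented.
* The genome-wide mutation scan tests marginal 2×2 association only; no
  covariate adjustment or mutual-exclusivity modelling.
* The pipeline's consensus stage subsamples samples only; feature
  subsampling is config-extensible but not implemented.
* Survival analysis assumes proportional hazards and right censoring
  independent of the event process.
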