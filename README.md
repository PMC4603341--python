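# pancimp

Pan-cancer analysis of the **CpG island methylator phenotype (CIMP)** — the
concerted hypermethylation of many promoter CpG islands (CGIs) in a subset
of tumors — from probe-level DNA methylation, gene expression, somatic
mutations, and clinical data.

The package is aimed at computational epigenomics researchers who want a
tested, reproducible implementation of the standard CIMP methodology and a
synthetic-data generator with planted ground truth to validate every stage.

## What it computes

1. **Probe → CGI aggregation.** 450K beta values β = M/(M+U) are averaged
   per CGI per sample, pooling island, shore (≤2 kb) and shelf (2–4 kb)
   probes.
2. **CIMP calling.** Per tissue, the *CIMP signature* is the top 5 % of
   CGIs by across-sample variance; Ward hierarchical clustering (Euclidean
   distance) of samples restricted to the signature is cut into two
   clusters, and the higher-methylation cluster is CIMP-positive.
3. **Cluster-number assessment.** Consensus clustering (100 resamples of
   80 % of samples) over K = 2…5; the area A(K) under the CDF of consensus
   entries and its relative increase Δ(K) — with Δ(2) = A(2) and
   Δ(K) = (A(K) − A(K−1))/A(K−1) — indicate the supported cluster number.
4. **Cross-cancer signature.** Per-tissue signatures are intersected; the
   observed overlap is compared against the analytic null N·p^T for T
   independent random p-subsets of N CGIs (plus a Monte-Carlo check), and
   all samples are re-clustered on the common signature.
5. **Expression-based prediction.** CIMP status is predicted from
   log2(RPKM+1)-standardized expression with L1-penalized logistic
   regression, fit per tissue (*lasso*), on pooled samples with per-tissue
   intercepts (*combined lasso*), or as a multi-task **group lasso**
   min Σ_t (1/(T·n_t)) Σ_i log(1+e^{−y·f_t(x)}) + λ√T Σ_g ‖w_g·‖₂,
   which forces a shared gene set with tissue-specific coefficients.
   Accuracy is measured by repeated stratified 3-fold CV against the
   majority-class baseline (one-sided one-sample Student t), and signature
   stability by 100 bootstrap refits (genes kept at ≥50 % frequency).
6. **Mutation association.** Per-gene two-sided hypergeometric tests of
   mutation × CIMP 2×2 tables with Benjamini-Hochberg correction, a
   candidate-gene panel (IDH1, IDH2, BRAF, KRAS, TET2), and Wilcoxon
   rank-sum comparison of per-sample mutation burden.
7. **Survival & clinical.** Kaplan-Meier curves, log-rank test, Cox
   proportional hazards (Efron ties, CIMP + age) and per-covariate
   Welch-t / chi-squared association tests (age, MSI, ER/PR/HER2, T/N/M).

A synthetic multi-tissue generator plants CIMP-positive subgroups,
hypermethylated CGI subsets (partially shared across tissues), predictive
genes, mutation enrichments, and survival effects, so each stage can be
checked against known truth.

## Worked example

```python
from pancimp import (SimulationConfig, simulate_dataset, aggregate_by_cgi,
                     filter_cgis, select_signature, call_cimp,
                     intersect_signatures)

ds = simulate_dataset(SimulationConfig(seed=0))
signatures = []
for tissue in ds.tissues:
    cgi = filter_cgis(aggregate_by_cgi(ds.probes[tissue], ds.annotation))
    sig = select_signature(cgi, fraction=0.05, tissue=tissue)
    call = call_cimp(cgi, sig, k=2)
    signatures.append(sig)
    print(call.summary())

overlap = intersect_signatures(signatures)
print(f"cross-cancer signature: {len(overlap.common_cgis)} CGIs "
      f"(random expectation {overlap.expected_overlap:.4f})")
```

prints

```
CIMP call — tissue=tissue1, k=2, n=200, signature=25 CGIs (5% most variant)
  cluster negative: n=149, mean signature methylation=0.198
  cluster positive: n=51, mean signature methylation=0.550
CIMP call — tissue=tissue2, k=2, n=200, signature=25 CGIs (5% most variant)
  cluster negative: n=141, mean signature methylation=0.197
  cluster positive: n=59, mean signature methylation=0.550
CIMP call — tissue=tissue3, k=2, n=200, signature=25 CGIs (5% most variant)
  cluster negative: n=133, mean signature methylation=0.200
  cluster positive: n=67, mean signature methylation=0.548
cross-cancer signature: 15 CGIs (random expectation 0.0625)
```

Each tissue's CIMP-positive cluster sits ~0.35 above the negative cluster in
mean signature methylation (the planted shift), the positive fractions track
the simulated 30 % prevalence, and the 15-CGI intersection — the planted
shared core — vastly exceeds the 0.0625 CGIs expected for random signatures.

The same analysis runs from the shell:

```bash
pancimp simulate --outdir data --seed 0
pancimp run-all --config config.yaml --outdir results
```

where `config.yaml` lists the per-tissue input files (see
`pancimp.pipeline.DEFAULTS` for every tunable and its default).

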