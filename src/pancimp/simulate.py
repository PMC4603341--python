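"""Synthetic multi-tissue methylation / expression / mutation / clinical data.

The generator plants a CIMP structure with known ground truth so that every
pipeline stage can be validated end to end:

* Each tissue cohort contains a CIMP-positive subgroup (Bernoulli with the
  configured prevalence) that is hypermethylated, by ``cimp_shift`` on the
  beta scale, on a planted subset of CGIs.  A configurable fraction of the
  planted CGIs is shared by all tissues — the cross-cancer signature.
* Background CGIs carry a fixed methylation mode (hypomethylated or
  hypermethylated beta distribution, one mode per CGI), matching the
  bimodal, but per-region stable, behaviour of 450K beta values.  Planted
  CGIs start from the hypomethylated mode, so the CIMP shift is additive
  with rare clipping and the CIMP+/− mean difference tracks ``cimp_shift``.
* Probe-level betas are the CGI value plus small Gaussian noise, clipped to
  [0, 1], so probe→CGI aggregation is meaningful.
* Expression is Gaussian per gene on the log2 scale and exponentiated to
  RPKM-like positives; a planted gene set shared across tissues is shifted
  by ``expression_effect`` standard deviations in CIMP+ samples.
* Mutations are per-gene Bernoulli; planted associated genes have their
  odds multiplied by ``mutation_odds_ratio`` in CIMP+ samples.
* Survival is exponential with hazard ratio ``survival_hr`` for CIMP+,
  censored by an independent uniform censoring time calibrated to the
  requested censoring fraction.

All randomness flows from a single ``numpy.random.default_rng(seed)``; the
draw order is: planted feature sets, probe annotation layout, then per
tissue (in order): labels, CGI betas, probe noise, expression, mutations,
clinical covariates, survival.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .matrices import CgiBetaMatrix, ProbeAnnotation, ProbeBetaMatrix


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_tissues: int = 3
    samples_per_tissue: tuple = (200, 200, 200)
    cimp_prevalence: float | tuple = 0.3
    n_cgis: int = 500
    n_probes_per_cgi: tuple = (3, 8)  # inclusive min/max
    signature_size: int = 25
    shared_signature_fraction: float = 0.6
    beta_background_hypo: tuple = (2.0, 8.0)
    beta_background_hyper: tuple = (8.0, 2.0)
    beta_hyper_weight: float = 0.3
    cimp_shift: float = 0.35
    probe_noise_sd: float = 0.03
    n_open_sea_probes: int = 50
    n_genes: int = 500
    n_predictive_genes: int = 20
    expression_effect: float = 1.5
    mutation_rate_background: float = 0.01
    n_assoc_mut_genes: int = 5
    mutation_odds_ratio: float = 8.0
    survival_hr: float = 1.0
    censoring_rate: float = 0.3
    cimp_age_shift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]

    def prevalence(self, tissue_index: int) -> float:
        if np.isscalar(self.cimp_prevalence):
            return float(self.cimp_prevalence)
        return float(self.cimp_prevalence[tissue_index])

    def validate(self) -> None:
        errors = []
        if self.n_tissues < 1:
            errors.append("n_tissues must be >= 1")
        if len(self.samples_per_tissue) != self.n_tissues:
            errors.append("samples_per_tissue length must equal n_tissues")
        if any(n < 2 for n in self.samples_per_tissue):
            errors.append("each tissue needs >= 2 samples")
        prevs = (
            [self.cimp_prevalence] * self.n_tissues
            if np.isscalar(self.cimp_prevalence)
            else list(self.cimp_prevalence)
        )
        if len(prevs) != self.n_tissues or any(not 0 <= p <= 1 for p in prevs):
            errors.append("cimp_prevalence must be fractions in [0,1], one per tissue")
        if self.n_cgis < 1 or self.signature_size < 1:
            errors.append("n_cgis and signature_size must be positive")
        if self.signature_size > self.n_cgis:
            errors.append("signature_size must be <= n_cgis")
        if not 0 <= self.shared_signature_fraction <= 1:
            errors.append("shared_signature_fraction must be in [0,1]")
        lo, hi = self.n_probes_per_cgi
        if lo < 1 or hi < lo:
            errors.append("n_probes_per_cgi must be (min, max) with 1 <= min <= max")
        if not 0 <= self.beta_hyper_weight <= 1:
            errors.append("beta_hyper_weight must be in [0,1]")
        if not 0 <= self.cimp_shift <= 1:
            errors.append("cimp_shift must be in [0,1]")
        if self.probe_noise_sd < 0:
            errors.append("probe_noise_sd must be >= 0")
        if self.n_predictive_genes > self.n_genes:
            errors.append("n_predictive_genes must be <= n_genes")
        if not 0 <= self.mutation_rate_background <= 1:
            errors.append("mutation_rate_background must be in [0,1]")
        if self.n_assoc_mut_genes > self.n_genes:
            errors.append("n_assoc_mut_genes must be <= n_genes")
        if self.mutation_odds_ratio <= 0:
            errors.append("mutation_odds_ratio must be > 0")
        if self.survival_hr <= 0:
            errors.append("survival_hr must be > 0")
        if not 0 <= self.censoring_rate < 1:
            errors.append("censoring_rate must be in [0,1)")
        if errors:
            raise ValueError("invalid SimulationConfig: " + "; ".join(errors))


@dataclass
class SyntheticDataset:
    """Generated cohorts plus the planted ground truth."""

    config: SimulationConfig
    annotation: ProbeAnnotation
    probes: dict[str, ProbeBetaMatrix]
    cgi_truth: dict[str, pd.DataFrame]  # noiseless CGI-level values
    expression: dict[str, pd.DataFrame]
    mutations: dict[str, pd.DataFrame]
    clinical: dict[str, pd.DataFrame]
    truth_labels: dict[str, pd.Series]  # "positive"/"negative" per sample
    planted_cgis: dict[str, list[str]]  # per tissue (includes shared core)
    shared_cgis: list[str]
    predictive_genes: list[str]
    mutation_genes: list[str]

    @property
    def tissues(self) -> list[str]:
        return list(self.probes)


def _baseline_hazard() -> float:
    # exponential baseline with ~1000-day median overall survival
    return np.log(2.0) / 1000.0


def _censor_horizon(lam: float, censoring_rate: float) -> float:
    """Uniform(0, c) horizon giving the requested expected censoring fraction
    under an exponential event-time with rate lam."""
    if censoring_rate <= 0:
        return np.inf
    f = lambda c: (1.0 - np.exp(-lam * c)) / (lam * c) - censoring_rate
    return brentq(f, 1e-9 / lam, 1e9 / lam)


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate a full multi-tissue dataset with planted CIMP structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cgi_ids = np.array([f"CGI{i:05d}" for i in range(config.n_cgis)])
    gene_ids = np.array([f"GENE{i:04d}" for i in range(config.n_genes)])

    # --- planted feature sets -------------------------------------------------
    n_shared = int(round(config.shared_signature_fraction * config.signature_size))
    shared_idx = rng.choice(config.n_cgis, size=n_shared, replace=False)
    planted_idx: dict[str, np.ndarray] = {}
    for t in range(config.n_tissues):
        pool = np.setdiff1d(np.arange(config.n_cgis), shared_idx)
        extra = rng.choice(pool, size=config.signature_size - n_shared, replace=False)
        planted_idx[config.tissues[t]] = np.sort(np.concatenate([shared_idx, extra]))
    predictive = np.sort(rng.choice(config.n_genes, config.n_predictive_genes, replace=False))
    assoc_mut = np.sort(rng.choice(config.n_genes, config.n_assoc_mut_genes, replace=False))

    # --- probe annotation layout (shared across tissues) ----------------------
    lo, hi = config.n_probes_per_cgi
    probes_per_cgi = rng.integers(lo, hi + 1, size=config.n_cgis)
    rel_choices = np.array(["island", "shore", "shelf"])
    rel_probs = np.array([0.6, 0.25, 0.15])
    rows = []
    pid = 0
    for i, cgi in enumerate(cgi_ids):
        chrom = f"chr{(i % 22) + 1}"
        start = 10_000 + 20_000 * (i // 22)
        for _ in range(probes_per_cgi[i]):
            rel = rng.choice(rel_choices, p=rel_probs)
            offset = {"island": 0, "shore": 1_500, "shelf": 3_000}[rel]
            rows.append(
                (f"cg{pid:08d}", chrom, start + offset + int(rng.integers(0, 500)),
                 cgi, rel, f"GENE{i % config.n_genes:04d}")
            )
            pid += 1
    for _ in range(config.n_open_sea_probes):
        rows.append(
            (f"cg{pid:08d}", f"chr{int(rng.integers(1, 23))}",
             int(rng.integers(1_000_000, 2_000_000)), None, "open_sea", "")
        )
        pid += 1
    annotation = ProbeAnnotation(
        pd.DataFrame(rows, columns=["probe_id", "chrom", "pos", "cgi_id", "relation", "genes"])
    )
    ann = annotation.frame
    cgi_of_probe = ann["cgi_id"]

    # per-CGI background mode: fixed across samples (regions are stably hypo- or
    # hyper-methylated); planted CGIs start hypomethylated so the CIMP shift is
    # visible and rarely clips
    hyper_mode = rng.random(config.n_cgis) < config.beta_hyper_weight
    all_planted = np.zeros(config.n_cgis, dtype=bool)
    for idx in planted_idx.values():
        all_planted[idx] = True
    hyper_mode[all_planted] = False
    a = np.where(hyper_mode, config.beta_background_hyper[0], config.beta_background_hypo[0])
    b = np.where(hyper_mode, config.beta_background_hyper[1], config.beta_background_hypo[1])

    # gene expression baselines (log2 scale)
    expr_mu = rng.normal(4.0, 2.0, size=config.n_genes)

    lam0 = _baseline_hazard()

    probes_out, cgi_out, expr_out, mut_out, clin_out, labels_out = {}, {}, {}, {}, {}, {}
    for t, tissue in enumerate(config.tissues):
        n = config.samples_per_tissue[t]
        samples = [f"{tissue}_S{i:03d}" for i in range(n)]
        is_pos = rng.random(n) < config.prevalence(t)
        labels = pd.Series(np.where(is_pos, "positive", "negative"), index=samples,
                           name="cimp_label")

        # CGI-level betas
        base = rng.beta(a[:, None], b[:, None], size=(config.n_cgis, n))
        planted_mask = np.zeros(config.n_cgis, dtype=bool)
        planted_mask[planted_idx[tissue]] = True
        shift = np.where(planted_mask[:, None] & is_pos[None, :], config.cimp_shift, 0.0)
        cgi_vals = np.clip(base + shift, 0.0, 1.0)
        cgi_df = pd.DataFrame(cgi_vals, index=cgi_ids, columns=samples)

        # probe-level betas = CGI value + noise; open-sea probes are uniform noise
        probe_vals = np.empty((len(ann), n))
        has_cgi = cgi_of_probe.notna().to_numpy()
        cgi_pos = pd.Index(cgi_ids).get_indexer(cgi_of_probe[has_cgi])
        noise = rng.normal(0.0, config.probe_noise_sd, size=(has_cgi.sum(), n))
        probe_vals[has_cgi] = np.clip(cgi_vals[cgi_pos] + noise, 0.0, 1.0)
        probe_vals[~has_cgi] = rng.random(((~has_cgi).sum(), n))
        probes_df = pd.DataFrame(probe_vals, index=ann.index, columns=samples)

        # expression: log2-Gaussian, planted genes shifted in CIMP+
        log2e = expr_mu[:, None] + rng.normal(0.0, 1.0, size=(config.n_genes, n))
        pred_mask = np.zeros(config.n_genes, dtype=bool)
        pred_mask[predictive] = True
        log2e += np.where(pred_mask[:, None] & is_pos[None, :], config.expression_effect, 0.0)
        rpkm = np.power(2.0, log2e)
        expr_df = pd.DataFrame(rpkm, index=gene_ids, columns=samples)

        # mutations: Bernoulli, odds-ratio enrichment for planted genes in CIMP+
        p = np.full((config.n_genes, n), config.mutation_rate_background)
        odds = config.mutation_rate_background / (1.0 - config.mutation_rate_background)
        p_enriched = (config.mutation_odds_ratio * odds) / (1.0 + config.mutation_odds_ratio * odds)
        assoc_mask = np.zeros(config.n_genes, dtype=bool)
        assoc_mask[assoc_mut] = True
        p[assoc_mask[:, None] & is_pos[None, :]] = p_enriched
        mut_df = pd.DataFrame((rng.random((config.n_genes, n)) < p).astype(int),
                              index=gene_ids, columns=samples)

        # clinical + survival
        age = rng.normal(63.0, 10.0, size=n) + np.where(is_pos, config.cimp_age_shift, 0.0)
        lam = lam0 * np.where(is_pos, config.survival_hr, 1.0)
        event_time = rng.exponential(1.0 / lam)
        horizon = _censor_horizon(lam0, config.censoring_rate)
        censor_time = rng.uniform(0.0, horizon, size=n) if np.isfinite(horizon) else np.full(n, np.inf)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
        clin_df = pd.DataFrame(
            {
                "sample_id": samples,
                "time": np.round(time, 1),
                "event": event,
                "age": np.round(age, 1),
                "msi": rng.choice(["MSS", "MSI-H"], size=n, p=[0.85, 0.15]),
                "er": rng.choice(["positive", "negative"], size=n, p=[0.7, 0.3]),
                "pr": rng.choice(["positive", "negative"], size=n, p=[0.65, 0.35]),
                "her2": rng.choice(["positive", "negative"], size=n, p=[0.2, 0.8]),
                "t_size": rng.choice(["T1", "T2", "T3", "T4"], size=n),
                "n_node": rng.choice(["N0", "N1"], size=n),
                "m_met": rng.choice(["M0", "M1"], size=n, p=[0.9, 0.1]),
                "tissue": tissue,
            }
        ).set_index("sample_id")

        probes_out[tissue] = ProbeBetaMatrix(beta=probes_df)
        cgi_out[tissue] = cgi_df
        expr_out[tissue] = expr_df
        mut_out[tissue] = mut_df
        clin_out[tissue] = clin_df
        labels_out[tissue] = labels

    return SyntheticDataset(
        config=config,
        annotation=annotation,
        probes=probes_out,
        cgi_truth=cgi_out,
        expression=expr_out,
        mutations=mut_out,
        clinical=clin_out,
        truth_labels=labels_out,
        planted_cgis={t: list(cgi_ids[idx]) for t, idx in planted_idx.items()},
        shared_cgis=list(cgi_ids[np.sort(shared_idx)]),
        predictive_genes=list(gene_ids[predictive]),
        mutation_genes=list(gene_ids[assoc_mut]),
    )


def simulate_clustered_cgi_matrix(
    n_samples: int = 120,
    n_clusters: int = 3,
    n_cgis: int = 400,
    n_marker_cgis: int = 10,
    marker_shift: float = 0.3,
    background_params: tuple = (2.0, 8.0),
    noise_sd: float = 0.02,
    seed=None,
):
    """CGI matrix with K planted methylation clusters on a shared marker set.

    Clusters form a methylation ladder on ``n_marker_cgis`` shared marker
    CGIs — the layout behind an *intermediate* methylation class: cluster
    j sits ``marker_shift``-spaced above the previous one, with widening
    gaps toward the top and mildly decreasing cluster sizes, so the ladder
    is a genuine K-cluster structure rather than a degenerate equidistant
    one.  Returns ``(CgiBetaMatrix, labels)`` with integer cluster labels.
    """
    rng = np.random.default_rng(seed)
    cgi_ids = [f"CGI{i:05d}" for i in range(n_cgis)]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    weights = np.linspace(1.25, 0.75, n_clusters)
    counts = np.floor(weights / weights.sum() * n_samples).astype(int)
    counts[0] += n_samples - counts.sum()
    labels = np.repeat(np.arange(n_clusters), counts)
    rng.shuffle(labels)
    offsets = np.concatenate(
        [[0.0], np.cumsum(marker_shift * 1.5 ** np.arange(n_clusters - 1))]
    )
    a, b = background_params
    base = rng.beta(a, b, size=(n_cgis, n_samples))
    base[:n_marker_cgis, :] += offsets[labels][None, :]
    vals = np.clip(base + rng.normal(0, noise_sd, size=base.shape), 0.0, 1.0)
    matrix = CgiBetaMatrix(beta=pd.DataFrame(vals, index=cgi_ids, columns=samples))
    return matrix, pd.Series(labels, index=samples, name="cluster")


def write_dataset(dataset: SyntheticDataset, directory) -> dict[str, Path]:
    """Write the dataset in the pipeline's TSV/CSV formats plus truth files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    ann_path = directory / "annotation.csv"
    dataset.annotation.to_csv(ann_path)
    paths["annotation"] = ann_path
    for tissue in dataset.tissues:
        p = directory / f"probes_{tissue}.tsv"
        dataset.probes[tissue].to_tsv(p)
        paths[f"probes_{tissue}"] = p
        e = directory / f"expression_{tissue}.tsv"
        dataset.expression[tissue].to_csv(e, sep="\t", index_label="gene_id")
        paths[f"expression_{tissue}"] = e
        m = directory / f"mutations_{tissue}.tsv"
        dataset.mutations[tissue].to_csv(m, sep="\t", index_label="gene_id")
        paths[f"mutations_{tissue}"] = m
        c = directory / f"clinical_{tissue}.tsv"
        dataset.clinical[tissue].to_csv(c, sep="\t")
        paths[f"clinical_{tissue}"] = c
        t = directory / f"truth_{tissue}.tsv"
        dataset.truth_labels[tissue].rename_axis("sample_id").to_frame().assign(
            tissue=tissue
        ).to_csv(t, sep="\t")
        paths[f"truth_{tissue}"] = t
    planted = directory / "truth_planted.json"
    planted.write_text(
        json.dumps(
            {
                "shared_cgis": dataset.shared_cgis,
                "planted_cgis": dataset.planted_cgis,
                "predictive_genes": dataset.predictive_genes,
                "mutation_genes": dataset.mutation_genes,
            },
            indent=1,
        )
    )
    paths["truth_planted"] = planted
    return paths
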