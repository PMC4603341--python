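"""End-to-end pipeline: aggregation → CIMP calls → consensus → cross-cancer
signature → expression prediction → mutation association → survival.

Configured from a flat YAML file whose defaults mirror the analysis
constants (5 % signature, K = 2..5, 100 consensus resamples at 80 %
subsampling, 100×3-fold CV, 100 bootstraps, 50 % signature-frequency
threshold, BH alpha 0.05, CGI missingness 0.3).  Every run writes a
manifest with SHA-256 content hashes of its outputs; identical config and
seed reproduce identical hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosscancer, mutation, survival
from .aggregate import aggregate_by_cgi, filter_cgis
from .cimp import call_cimp, select_signature, signature_stability
from .consensus import ConsensusCluster
from .matrices import CgiBetaMatrix, ProbeAnnotation, ProbeBetaMatrix
from .prediction import (
    bootstrap_signature,
    compare_method_signatures,
    evaluate_cv,
    prepare_features,
)

log = logging.getLogger("pancimp")

STAGES = (
    "aggregate",
    "cimp",
    "consensus",
    "cross_signature",
    "expression_prediction",
    "mutation_association",
    "survival_clinical",
)

DEFAULTS = {
    "signature_fraction": 0.05,
    "k_min": 2,
    "k_max": 5,
    "consensus_resamples": 100,
    "consensus_subsample_fraction": 0.8,
    "cv_repeats": 100,
    "cv_folds": 3,
    "n_bootstraps": 100,
    "n_lambdas": 50,
    "lambda_min_ratio": 0.01,
    "signature_frequency_threshold": 0.5,
    "bh_alpha": 0.05,
    "max_missing_fraction": 0.3,
    "min_mutated": 3,
    "monte_carlo_reps": 2000,
    "seed": 0,
}

_RANGES = {
    "signature_fraction": (0.0, 1.0),
    "consensus_subsample_fraction": (0.0, 1.0),
    "signature_frequency_threshold": (0.0, 1.0),
    "bh_alpha": (0.0, 1.0),
    "max_missing_fraction": (0.0, 1.0),
    "lambda_min_ratio": (0.0, 1.0),
}


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Validated, default-filled pipeline configuration."""

    annotation: Path
    tissues: dict  # tissue → {probes, expression, mutations, clinical} paths
    outdir: Path = Path("pancimp_out")
    params: dict = field(default_factory=lambda: dict(DEFAULTS))

    def __post_init__(self):
        for key, value in self.params.items():
            if key not in DEFAULTS:
                raise ValueError(f"unknown config key: {key}")
            if key in _RANGES:
                lo, hi = _RANGES[key]
                if not lo <= value <= hi:
                    raise ValueError(f"config key {key}={value} outside [{lo}, {hi}]")
        if self.params["k_min"] > self.params["k_max"]:
            raise ValueError("empty K range: k_min > k_max")
        if self.params["k_min"] < 2:
            raise ValueError("k_min must be >= 2")
        missing = [str(p) for p in self._referenced_paths() if not Path(p).exists()]
        if missing:
            raise ValueError(f"referenced files do not exist: {missing}")

    def _referenced_paths(self):
        paths = [self.annotation]
        for files in self.tissues.values():
            paths.extend(files.values())
        return paths

    @property
    def k_range(self):
        return range(self.params["k_min"], self.params["k_max"] + 1)


def validate_config(path) -> PipelineConfig:
    """Load a YAML config, fill defaults, check ranges, resolve paths."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    base = path.parent

    def resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    known_top = {"annotation", "tissues", "outdir"} | set(DEFAULTS)
    unknown = set(raw) - known_top
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "annotation" not in raw or "tissues" not in raw:
        raise ValueError("config must define 'annotation' and 'tissues'")
    tissues = {
        t: {k: resolve(v) for k, v in files.items()}
        for t, files in raw["tissues"].items()
    }
    params = dict(DEFAULTS)
    params.update({k: raw[k] for k in DEFAULTS if k in raw})
    return PipelineConfig(
        annotation=resolve(raw["annotation"]),
        tissues=tissues,
        outdir=resolve(raw.get("outdir", "pancimp_out")),
        params=params,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_signature_bed(signature, annotation: ProbeAnnotation, path: Path) -> None:
    """Signature CGIs as 0-based half-open intervals spanning their probes."""
    ann = annotation.frame.dropna(subset=["cgi_id"])
    rows = []
    for cgi in signature.cgi_ids:
        sub = ann[ann["cgi_id"] == cgi]
        if sub.empty:
            continue
        rows.append((sub["chrom"].iloc[0], int(sub["pos"].min()) - 1,
                     int(sub["pos"].max()), cgi))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]).to_csv(
        path, sep="\t", header=False, index=False
    )


class PipelineRun:
    """Stateful pipeline execution over one configured dataset."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.summary: dict = {"seed": config.params["seed"], "stages": {}}
        self.outputs: list[Path] = []
        self.completed: list[str] = []
        self._seedseq = np.random.SeedSequence(config.params["seed"])
        # fixed spawn order keeps per-stage streams independent of stage selection
        self._stage_seeds = {
            s: int(ss.generate_state(1)[0] % (2 ** 31))
            for s, ss in zip(STAGES, self._seedseq.spawn(len(STAGES)))
        }
        self.cgi: dict[str, CgiBetaMatrix] = {}
        self.signatures: dict = {}
        self.calls: dict = {}

    # -- stages ---------------------------------------------------------------
    def stage_aggregate(self):
        p = self.config.params
        annotation = ProbeAnnotation.read_csv(self.config.annotation)
        self.annotation = annotation
        block = {}
        for tissue, files in self.config.tissues.items():
            probes = ProbeBetaMatrix.read_tsv(files["probes"])
            agg = aggregate_by_cgi(probes, annotation)
            self.cgi[tissue] = filter_cgis(agg, p["max_missing_fraction"])
            out = self.outdir / f"cgi_beta_{tissue}.tsv"
            self.cgi[tissue].to_tsv(out)
            self.outputs.append(out)
            block[tissue] = {
                "n_probes": len(probes.probe_ids),
                "n_cgis": len(self.cgi[tissue].cgi_ids),
                "n_samples": len(self.cgi[tissue].sample_ids),
            }
        return block

    def stage_cimp(self):
        p = self.config.params
        block = {}
        frames = []
        for tissue, matrix in self.cgi.items():
            sig = select_signature(matrix, p["signature_fraction"], tissue=tissue)
            call = call_cimp(matrix, sig, k=2)
            self.signatures[tissue] = sig
            self.calls[tissue] = call
            frames.append(call.to_frame())
            sig_path = self.outdir / f"signature_{tissue}.tsv"
            sig.to_frame().to_csv(sig_path, sep="\t", index=False)
            bed_path = self.outdir / f"signature_{tissue}.bed"
            _write_signature_bed(sig, self.annotation, bed_path)
            self.outputs.extend([sig_path, bed_path])
            block[tissue] = {
                "signature_size": len(sig),
                "n_positive": int((call.labels == "positive").sum()),
                "n_negative": int((call.labels == "negative").sum()),
                "positive_fraction": call.positive_fraction,
            }
        calls_path = self.outdir / "cimp_calls.tsv"
        pd.concat(frames).to_csv(calls_path, sep="\t")
        self.outputs.append(calls_path)
        return block

    def stage_consensus(self):
        p = self.config.params
        seed = self._stage_seeds["consensus"]
        block = {}
        for i, (tissue, matrix) in enumerate(self.cgi.items()):
            model = ConsensusCluster(
                matrix,
                self.signatures[tissue],
                k_range=self.config.k_range,
                n_resamples=p["consensus_resamples"],
                subsample_fraction=p["consensus_subsample_fraction"],
            )
            res = model.fit(seed=seed + i)
            stability = signature_stability(matrix, tissue=tissue)
            block[tissue] = {
                "areas": {str(k): v for k, v in res.areas.items()},
                "deltas": {str(k): v for k, v in res.deltas.items()},
                "best_k": res.best_k(),
                "stability_ari": {f"{f:.2f}": v for f, v in stability.items()},
            }
        return block

    def stage_cross_signature(self):
        p = self.config.params
        if len(self.signatures) < 2:
            return {"skipped": "needs >= 2 tissues"}
        overlap = crosscancer.intersect_signatures(list(self.signatures.values()))
        mean_frac = float(np.mean(
            [len(s) / overlap.n_total_cgis for s in self.signatures.values()]
        ))
        mc = crosscancer.monte_carlo_overlap(
            overlap.n_total_cgis, mean_frac, len(self.signatures),
            n_reps=max(100, p["monte_carlo_reps"]),
            seed=self._stage_seeds["cross_signature"],
        )
        block = overlap.to_dict()
        block["monte_carlo"] = mc
        common_path = self.outdir / "cross_cancer_signature.tsv"
        pd.Series(sorted(overlap.common_cgis), name="cgi_id").to_csv(
            common_path, sep="\t", index=False
        )
        self.outputs.append(common_path)
        if overlap.common_cgis:
            pooled = crosscancer.pan_cancer_call(self.cgi, overlap.common_cgis)
            tab = crosscancer.cross_tabulate(
                pooled, {t: c.labels for t, c in self.calls.items()}
            )
            block["pan_cancer"] = {
                "n_positive": int((pooled.labels == "positive").sum()),
                "n_negative": int((pooled.labels == "negative").sum()),
                "cross_tab": {
                    f"{t}|{lab}": row.to_dict() for (t, lab), row in tab.iterrows()
                },
            }
        overlap_path = self.outdir / "overlap_report.json"
        overlap_path.write_text(json.dumps(block, indent=1, default=str))
        self.outputs.append(overlap_path)
        return block

    def stage_expression_prediction(self):
        p = self.config.params
        seed = self._stage_seeds["expression_prediction"]
        tasks = []
        for tissue, files in self.config.tissues.items():
            if "expression" not in files:
                raise FileNotFoundError(f"no expression file for {tissue}")
            expr = pd.read_csv(files["expression"], sep="\t", index_col=0)
            task = prepare_features(expr, self.calls[tissue].labels, tissue=tissue)
            if task.y.value_counts().min() < p["cv_folds"]:
                log.warning("tissue %s excluded from prediction (class too small)",
                            tissue)
                continue
            tasks.append(task)
        if not tasks:
            raise ValueError("no tissue is eligible for expression prediction")
        block = {}
        reports = {}
        cv_kwargs = dict(
            n_repeats=p["cv_repeats"], n_folds=p["cv_folds"],
            n_lambdas=p["n_lambdas"], lambda_min_ratio=p["lambda_min_ratio"],
        )
        for i, task in enumerate(tasks):
            rep = evaluate_cv(task, "lasso", seed=seed + i, **cv_kwargs)
            rep.bootstrap_frequencies = bootstrap_signature(
                task, "lasso", n_boot=p["n_bootstraps"], seed=seed + 1000 + i,
                n_lambdas=p["n_lambdas"], lambda_min_ratio=p["lambda_min_ratio"],
            )
            block[f"lasso_{task.tissue}"] = _report_block(rep)
        if len(tasks) >= 2:
            for j, method in enumerate(("combined_lasso", "group_lasso")):
                rep = evaluate_cv(tasks, method, seed=seed + 2000 + j, **cv_kwargs)
                rep.bootstrap_frequencies = bootstrap_signature(
                    tasks, method, n_boot=p["n_bootstraps"], seed=seed + 3000 + j,
                    n_lambdas=p["n_lambdas"], lambda_min_ratio=p["lambda_min_ratio"],
                )
                reports[method] = rep
                block[method] = _report_block(rep)
                sig_path = self.outdir / f"gene_signature_{method}.tsv"
                rep.bootstrap_frequencies.sort_values(ascending=False).to_csv(
                    sig_path, sep="\t", header=["frequency"]
                )
                self.outputs.append(sig_path)
            block["method_comparison"] = compare_method_signatures(reports)
        return block

    def stage_mutation_association(self):
        p = self.config.params
        block = {}
        muts = {}
        for tissue, files in self.config.tissues.items():
            if "mutations" not in files:
                raise FileNotFoundError(f"no mutation file for {tissue}")
            mut = pd.read_csv(files["mutations"], sep="\t", index_col=0)
            muts[tissue] = mut
            scan = mutation.genomewide_mutation_scan(
                mut, self.calls[tissue].labels, min_mutated=p["min_mutated"]
            )
            scan_path = self.outdir / f"mutation_scan_{tissue}.tsv"
            scan.to_csv(scan_path, sep="\t")
            self.outputs.append(scan_path)
            burden = mutation.burden_comparison(mut, self.calls[tissue].labels)
            block[tissue] = {
                "n_tested": int(len(scan)),
                "n_significant": int((scan["q"] < p["bh_alpha"]).sum()),
                "burden": burden,
            }
        cand = mutation.candidate_gene_table(
            muts, {t: c.labels for t, c in self.calls.items()}
        )
        cand_path = self.outdir / "candidate_gene_table.tsv"
        cand.to_csv(cand_path, sep="\t")
        self.outputs.append(cand_path)
        block["candidate_genes"] = {
            f"{g}|{t}": {"status": r["status"], "p": None if pd.isna(r["p"]) else r["p"]}
            for (g, t), r in cand.iterrows()
        }
        return block

    def stage_survival_clinical(self):
        block = {}
        for tissue, files in self.config.tissues.items():
            if "clinical" not in files:
                raise FileNotFoundError(f"no clinical file for {tissue}")
            clin = pd.read_csv(files["clinical"], sep="\t", index_col=0)
            labels = self.calls[tissue].labels
            surv = survival.survival_analysis(clin, labels)
            assoc = survival.clinical_associations(labels, clin)
            assoc_path = self.outdir / f"clinical_associations_{tissue}.tsv"
            assoc.to_csv(assoc_path, sep="\t")
            self.outputs.append(assoc_path)
            block[tissue] = {
                "logrank": surv["logrank"],
                "cox": {
                    "log_hr": surv["cox"].log_hr,
                    "hr": surv["cox"].hr,
                    "ci": [surv["cox"].ci_low, surv["cox"].ci_high],
                    "p": surv["cox"].p_value,
                },
                "clinical_tests": {
                    c: {"p": None if pd.isna(r["p_value"]) else r["p_value"],
                        "status": r["status"]}
                    for c, r in assoc.iterrows()
                },
            }
        return block

    # -- driver ---------------------------------------------------------------
    def run(self, stages=None) -> dict:
        todo = list(stages) if stages else list(STAGES)
        unknown = set(todo) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        # dependency closure: everything needs aggregate + cimp
        for dep in ("cimp", "aggregate"):
            if dep not in todo:
                todo.insert(0, dep)
        todo = [s for s in STAGES if s in todo]
        for stage in todo:
            log.info("running stage %s (seed %d)", stage, self._stage_seeds[stage])
            try:
                self.summary["stages"][stage] = getattr(self, f"stage_{stage}")()
            except Exception as exc:  # noqa: BLE001 — halt with stage context
                self._write_manifest()
                raise PipelineStageError(stage, exc) from exc
            self.completed.append(stage)
        self._write_summary()
        self._write_manifest()
        return self.summary

    def _write_summary(self):
        path = self.outdir / "summary.json"
        path.write_text(json.dumps(self.summary, indent=1, default=_jsonable))
        self.outputs.append(path)

    def _write_manifest(self):
        manifest = {
            "completed_stages": self.completed,
            "outputs": {str(p.name): _sha256(p) for p in self.outputs if p.exists()},
        }
        (self.outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Series)):
        return np.asarray(obj).tolist()
    return str(obj)


def _report_block(rep) -> dict:
    freq = rep.bootstrap_frequencies
    return {
        "mean_accuracy": rep.mean_accuracy,
        "baseline_accuracy": rep.baseline_accuracy,
        "p_value": rep.p_value,
        "signature_size": len(rep.signature),
        "top_genes": (
            freq.sort_values(ascending=False).head(10).to_dict() if freq is not None else {}
        ),
    }


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Execute the configured stages; returns the summary dictionary."""
    return PipelineRun(config).run(stages=stages)
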