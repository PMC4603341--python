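"""Probe-level to CGI-level methylation aggregation.

The 450K array reports, for each CpG probe, a methylated intensity M and an
unmethylated intensity U; the beta value M/(M+U) estimates the methylation
fraction at that CpG.  CIMP analysis works at the CpG-island level: every
probe annotated to a CGI — including its flanking shores (within 2 kb) and
shelves (2–4 kb) — contributes to a single per-CGI, per-sample methylation
level, taken as the arithmetic mean of the non-missing probe betas.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .matrices import CgiBetaMatrix, ProbeAnnotation, ProbeBetaMatrix


def compute_beta(methylated, unmethylated):
    """Beta value M/(M+U) for methylated/unmethylated intensities.

    Accepts scalars or arrays.  Where M + U == 0 the beta value is undefined
    and NaN is returned rather than raising.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    total = m + u
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(total > 0, m / np.where(total > 0, total, 1.0), np.nan)
    if beta.ndim == 0:
        return float(beta)
    return beta


def aggregate_by_cgi(
    probes: ProbeBetaMatrix,
    annotation: ProbeAnnotation,
    include_shores_shelves: bool = True,
) -> CgiBetaMatrix:
    """Mean probe beta per CGI per sample.

    Open-sea probes never contribute.  With ``include_shores_shelves=False``
    only ``relation == "island"`` probes contribute; otherwise island, shore
    and shelf probes are pooled.  Missing probe values are ignored in the
    mean; a CGI appears in the output only if it has at least one assigned
    probe with at least one observed value somewhere.
    """
    unknown = probes.probe_ids.difference(annotation.probe_ids)
    if len(unknown):
        raise ValueError(
            f"{len(unknown)} probes missing from annotation, e.g. {list(unknown[:5])}"
        )
    ann = annotation.frame.loc[probes.probe_ids]
    if include_shores_shelves:
        keep = ann["relation"].isin(["island", "shore", "shelf"])
    else:
        keep = ann["relation"] == "island"
    keep &= ann["cgi_id"].notna()
    if not keep.any():
        raise ValueError("no probes assigned to any CGI after filtering")
    sub = probes.beta.loc[keep.index[keep]]
    groups = ann.loc[keep, "cgi_id"]
    agg = sub.groupby(groups).mean()  # skipna by default: missing-aware mean
    n_probes = sub.notna().any(axis=1).groupby(groups).sum()
    nonempty = agg.notna().any(axis=1)
    return CgiBetaMatrix(beta=agg.loc[nonempty], n_probes=n_probes.loc[nonempty])


def filter_cgis(matrix: CgiBetaMatrix, max_missing_fraction: float = 0.3) -> CgiBetaMatrix:
    """Drop high-missingness CGIs, then mean-impute the rest.

    A CGI is dropped when its fraction of missing samples exceeds
    ``max_missing_fraction``; remaining missing entries are imputed with the
    CGI's mean over observed samples (per cohort, since a matrix holds one
    tissue cohort).
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    miss_frac = matrix.beta.isna().mean(axis=1)
    keep = miss_frac <= max_missing_fraction
    if not keep.any():
        raise ValueError("all CGIs exceed the missingness threshold")
    beta = matrix.beta.loc[keep]
    row_means = beta.mean(axis=1)
    beta = beta.apply(lambda row: row.fillna(row_means[row.name]), axis=1)
    return CgiBetaMatrix(beta=beta, n_probes=matrix.n_probes.loc[keep])
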