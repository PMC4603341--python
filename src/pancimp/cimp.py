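"""CIMP signature selection and CIMP-positive/negative calling.

A CpG island methylator phenotype (CIMP) shows up as joint hypermethylation
of a subset of CGIs in a subset of tumors.  Calling proceeds in two steps:

1. *Signature*: the top fraction (default 5 %) of CGIs by across-sample
   variance within a tissue cohort.
2. *Call*: Ward hierarchical clustering (Euclidean distance) of samples
   restricted to the signature CGIs, tree cut at k clusters.  For k = 2 the
   cluster with the higher mean signature methylation is CIMP-positive; for
   k > 2 clusters are numbered 1..k by increasing mean methylation.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from .matrices import CgiBetaMatrix

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass
class CimpSignature:
    """The most variant CGIs of one tissue cohort."""

    tissue: str
    cgi_ids: list[str]
    variance_fraction: float
    variances: pd.Series  # sorted non-increasing, indexed by cgi_id

    def __len__(self) -> int:
        return len(self.cgi_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cgi_id": self.cgi_ids, "variance": self.variances.loc[self.cgi_ids].values}
        )


def select_signature(
    matrix: CgiBetaMatrix, fraction: float = 0.05, tissue: str = ""
) -> CimpSignature:
    """Top ``ceil(fraction * n_cgis)`` CGIs by unbiased sample variance.

    Ties at the cutoff variance break lexicographically by CGI id, so the
    selection is deterministic.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.beta.shape[1] < 2:
        raise ValueError("variance undefined with fewer than 2 samples")
    variances = matrix.beta.var(axis=1, ddof=1)
    n_keep = math.ceil(fraction * len(variances))
    order = variances.to_frame("var").reset_index()
    order.columns = ["cgi_id", "var"]
    order = order.sort_values(["var", "cgi_id"], ascending=[False, True], kind="mergesort")
    chosen = order.head(n_keep)["cgi_id"].tolist()
    return CimpSignature(
        tissue=tissue,
        cgi_ids=chosen,
        variance_fraction=fraction,
        variances=variances.sort_values(ascending=False, kind="mergesort"),
    )


class CimpClusterModel:
    """Ward/Euclidean clustering of samples on a CIMP signature.

    Parameters
    ----------
    matrix : CgiBetaMatrix
        CGI × sample methylation for one cohort (or a pooled cohort).
    signature : CimpSignature
        CGIs on which samples are clustered; all must be rows of ``matrix``.
    """

    def __init__(self, matrix: CgiBetaMatrix, signature: CimpSignature):
        missing = [c for c in signature.cgi_ids if c not in matrix.beta.index]
        if missing:
            raise ValueError(f"signature CGIs absent from matrix: {missing[:5]}")
        self.matrix = matrix
        self.signature = signature
        # samples × signature CGIs
        self.features = matrix.beta.loc[signature.cgi_ids].T

    def fit(self, k: int = 2) -> "CimpResults":
        X = self.features.to_numpy(dtype=float)
        n = X.shape[0]
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > n:
            raise ValueError(f"k={k} exceeds the number of samples ({n})")
        if np.allclose(X, X[0], atol=1e-12):
            raise ValueError("no methylation variation: all samples identical")
        Z = linkage(X, method="ward", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust")
        # order clusters by mean signature methylation, ascending
        means = pd.Series(X.mean(axis=1)).groupby(raw).mean()
        rank = {c: i + 1 for i, c in enumerate(means.sort_values().index)}
        ordered = np.array([rank[c] for c in raw])
        cluster_means = pd.Series(
            {rank[c]: m for c, m in means.items()}, name="mean_methylation"
        ).sort_index()
        if k == 2:
            labels = pd.Series(
                np.where(ordered == 2, POSITIVE, NEGATIVE),
                index=self.features.index,
                name="cimp_label",
            )
            assert cluster_means[2] > cluster_means[1], "labeling rule violated"
            cluster_means.index = [NEGATIVE, POSITIVE]
        else:
            labels = pd.Series(ordered, index=self.features.index, name="cimp_label")
        return CimpResults(
            tissue=self.signature.tissue,
            labels=labels,
            signature=self.signature,
            cluster_mean_methylation=cluster_means,
            k=k,
        )


@dataclass
class CimpResults:
    """Per-sample CIMP labels plus the signature that produced them."""

    tissue: str
    labels: pd.Series
    signature: CimpSignature
    cluster_mean_methylation: pd.Series
    k: int = 2

    @property
    def sample_ids(self) -> pd.Index:
        return self.labels.index

    @property
    def positive_fraction(self) -> float:
        if self.k != 2:
            raise ValueError("positive_fraction defined only for k=2 calls")
        return float((self.labels == POSITIVE).mean())

    def to_frame(self) -> pd.DataFrame:
        df = self.labels.to_frame()
        df.insert(0, "tissue", self.tissue)
        df["cluster_mean_methylation"] = self.labels.map(self.cluster_mean_methylation)
        return df.rename_axis("sample_id")

    def summary(self) -> str:
        counts = self.labels.value_counts().to_dict()
        lines = [
            f"CIMP call — tissue={self.tissue or '<unnamed>'}, k={self.k}, "
            f"n={len(self.labels)}, signature={len(self.signature)} CGIs "
            f"({self.signature.variance_fraction:.0%} most variant)",
        ]
        for cluster, mean in self.cluster_mean_methylation.items():
            lines.append(
                f"  cluster {cluster}: n={counts.get(cluster, 0)}, "
                f"mean signature methylation={mean:.3f}"
            )
        return "\n".join(lines)


def call_cimp(matrix: CgiBetaMatrix, signature: CimpSignature, k: int = 2) -> CimpResults:
    """Cluster samples on the signature and label CIMP status (see module doc)."""
    return CimpClusterModel(matrix, signature).fit(k=k)


def signature_stability(
    matrix: CgiBetaMatrix,
    fractions=(0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09, 0.10),
    reference_fraction: float = 0.05,
    tissue: str = "",
) -> pd.Series:
    """ARI of the k=2 call at each signature size against the reference call.

    Quantifies how sensitive the CIMP partition is to the exact size of the
    signature (the fraction of most-variant CGIs retained).
    """
    ref_sig = select_signature(matrix, reference_fraction, tissue=tissue)
    ref_call = call_cimp(matrix, ref_sig)
    out = {}
    for frac in fractions:
        sig = select_signature(matrix, frac, tissue=tissue)
        call = call_cimp(matrix, sig)
        out[frac] = adjusted_rand_score(ref_call.labels.values, call.labels.values)
    return pd.Series(out, name="ari_vs_reference").rename_axis("fraction")
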