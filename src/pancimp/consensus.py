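"""Consensus clustering for cluster-number assessment (Monti et al. style).

For each candidate cluster number K, samples are repeatedly subsampled
without replacement and re-clustered; the consensus matrix records, for each
pair of samples, the fraction of co-subsampled runs in which they landed in
the same cluster.  A clean K-cluster structure drives consensus entries to
0 or 1.  The empirical CDF of the off-diagonal consensus entries summarises
this: its area A(K) grows as the clustering stabilises, and the relative
area increase

    Δ(2) = A(2),   Δ(K) = (A(K) − A(K−1)) / A(K−1)   for K ≥ 3

peaks at the number of clusters supported by the data.

A(K) is the exact integral of the empirical CDF over [0, 1], which for
entries e_1..e_m equals 1 − mean(e); a fixed-grid CDF is also stored for
plotting/reporting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cimp import CimpSignature
from .matrices import CgiBetaMatrix


def delta_k(areas: dict[int, float]) -> dict[int, float]:
    """Relative increase of the consensus-CDF area per candidate K.

    ``areas`` maps contiguous K values starting at 2 to A(K).
    """
    ks = sorted(areas)
    if not ks or ks[0] != 2 or ks != list(range(2, ks[-1] + 1)):
        raise ValueError("areas must cover contiguous K starting at 2")
    deltas = {2: areas[2]}
    for k in ks[1:]:
        prev = areas[k - 1]
        if prev == 0:
            raise ValueError(f"A({k - 1}) = 0: delta undefined")
        deltas[k] = (areas[k] - prev) / prev
    return deltas


@dataclass
class ConsensusResults:
    """Consensus matrices, CDFs, A(K) and Δ(K) over a K range."""

    consensus: dict[int, pd.DataFrame]
    cdf_grid: np.ndarray
    cdfs: dict[int, np.ndarray]
    areas: dict[int, float]
    deltas: dict[int, float]
    n_resamples: int
    subsample_fraction: float

    @property
    def k_range(self) -> list[int]:
        return sorted(self.consensus)

    def best_k(self) -> int:
        """K at which Δ(K) is maximal (ties → smaller K)."""
        return max(sorted(self.deltas), key=lambda k: (self.deltas[k], -k))

    def summary(self) -> str:
        lines = [
            f"Consensus clustering — {self.n_resamples} resamples, "
            f"{self.subsample_fraction:.0%} subsampling"
        ]
        for k in self.k_range:
            lines.append(f"  K={k}: A={self.areas[k]:.4f}  delta={self.deltas[k]:.4f}")
        lines.append(f"  suggested K = {self.best_k()}")
        return "\n".join(lines)


class ConsensusCluster:
    """Subsampled Ward co-clustering over a range of cluster numbers.

    Parameters follow the consensus-clustering convention: 100 resamples of
    80 % of samples (no feature subsampling), K from 2 to 5.
    """

    def __init__(
        self,
        matrix: CgiBetaMatrix,
        signature: CimpSignature,
        k_range=range(2, 6),
        n_resamples: int = 100,
        subsample_fraction: float = 0.8,
        grid_points: int = 101,
    ):
        if n_resamples < 2:
            raise ValueError("n_resamples must be >= 2")
        if not 0 < subsample_fraction <= 1:
            raise ValueError("subsample_fraction must be in (0, 1]")
        missing = [c for c in signature.cgi_ids if c not in matrix.beta.index]
        if missing:
            raise ValueError(f"signature CGIs absent from matrix: {missing[:5]}")
        self.features = matrix.beta.loc[signature.cgi_ids].T
        self.k_range = list(k_range)
        self.n_resamples = n_resamples
        self.subsample_fraction = subsample_fraction
        self.grid = np.linspace(0.0, 1.0, grid_points)

    def fit(self, seed: int | np.random.Generator | None = None) -> ConsensusResults:
        rng = np.random.default_rng(seed)
        X = self.features.to_numpy(dtype=float)
        n = X.shape[0]
        m = max(1, int(round(self.subsample_fraction * n)))
        consensus, cdfs, areas = {}, {}, {}
        for k in self.k_range:
            co_cluster = np.zeros((n, n))
            co_sample = np.zeros((n, n))
            n_done = 0
            for _ in range(self.n_resamples):
                idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
                if m < k:
                    warnings.warn(
                        f"subsample of {m} too small for K={k}; resample skipped"
                    )
                    continue
                Z = linkage(X[idx], method="ward", metric="euclidean")
                lab = fcluster(Z, t=k, criterion="maxclust")
                same = (lab[:, None] == lab[None, :]).astype(float)
                co_cluster[np.ix_(idx, idx)] += same
                co_sample[np.ix_(idx, idx)] += 1.0
                n_done += 1
            if n_done == 0:
                raise ValueError(f"all resamples skipped for K={k}")
            with np.errstate(invalid="ignore", divide="ignore"):
                cons = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), np.nan)
            consensus[k] = pd.DataFrame(
                cons, index=self.features.index, columns=self.features.index
            )
            iu = np.triu_indices(n, k=1)
            entries = cons[iu]
            entries = entries[np.isfinite(entries)]
            if entries.size == 0:
                raise ValueError(f"no pair was ever co-sampled at K={k}")
            cdfs[k] = np.array([(entries <= t).mean() for t in self.grid])
            areas[k] = float(1.0 - entries.mean())  # exact CDF integral over [0,1]
        return ConsensusResults(
            consensus=consensus,
            cdf_grid=self.grid,
            cdfs=cdfs,
            areas=areas,
            deltas=delta_k(areas),
            n_resamples=self.n_resamples,
            subsample_fraction=self.subsample_fraction,
        )


def consensus_cluster(
    matrix: CgiBetaMatrix,
    signature: CimpSignature,
    k_range=range(2, 6),
    n_resamples: int = 100,
    subsample_fraction: float = 0.8,
    seed=None,
) -> ConsensusResults:
    """Functional wrapper around :class:`ConsensusCluster`."""
    model = ConsensusCluster(
        matrix, signature, k_range=k_range, n_resamples=n_resamples,
        subsample_fraction=subsample_fraction,
    )
    return model.fit(seed=seed)
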