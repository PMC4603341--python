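"""Cross-cancer signature intersection and the random-overlap null.

If per-tissue CIMP signatures were independent uniformly random subsets,
each containing a fraction p of the N CGIs, the expected size of their
T-way intersection would be N·p^T.  Comparing the observed intersection to
this null quantifies whether a shared epigenetic signature exists.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .cimp import CimpResults, CimpSignature, call_cimp
from .matrices import CgiBetaMatrix


@dataclass
class SignatureOverlap:
    tissue_signatures: list[CimpSignature]
    common_cgis: set[str]
    pairwise_counts: dict[tuple[str, str], int]
    n_total_cgis: int
    expected_overlap: float

    def to_dict(self) -> dict:
        return {
            "signature_sizes": {s.tissue: len(s) for s in self.tissue_signatures},
            "common_size": len(self.common_cgis),
            "common_cgis": sorted(self.common_cgis),
            "pairwise_counts": {f"{a}|{b}": v for (a, b), v in self.pairwise_counts.items()},
            "n_total_cgis": self.n_total_cgis,
            "expected_overlap": self.expected_overlap,
        }


def expected_random_overlap(n_total: int, fraction: float, n_sets: int) -> float:
    """Expected T-way intersection size of random p-subsets: N · p^T."""
    if n_total < 1:
        raise ValueError("n_total must be >= 1")
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    return n_total * fraction ** n_sets


def intersect_signatures(signatures: list[CimpSignature]) -> SignatureOverlap:
    """Exact intersection of per-tissue signatures plus pairwise overlap counts.

    Signatures must share a CGI universe; fully disjoint universes (no CGI in
    common between any pair of the underlying variance tables) are rejected.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures")
    universes = [set(s.variances.index) for s in signatures]
    common_universe = set.intersection(*universes)
    if not common_universe:
        raise ValueError("signatures are over disjoint CGI universes")
    sets = [set(s.cgi_ids) for s in signatures]
    common = set.intersection(*sets)
    names = [s.tissue or f"tissue{i}" for i, s in enumerate(signatures)]
    pairwise = {
        (names[i], names[j]): len(sets[i] & sets[j])
        for i, j in combinations(range(len(sets)), 2)
    }
    n_total = len(set.union(*universes))
    mean_fraction = float(np.mean([len(s) / n_total for s in sets]))
    expected = expected_random_overlap(n_total, mean_fraction, len(sets))
    return SignatureOverlap(
        tissue_signatures=signatures,
        common_cgis=common,
        pairwise_counts=pairwise,
        n_total_cgis=n_total,
        expected_overlap=expected,
    )


def monte_carlo_overlap(
    n_total: int, fraction: float, n_sets: int, n_reps: int = 10_000, seed=None
) -> dict:
    """Monte-Carlo estimate of the random-overlap null (mean ± SE).

    Draws ``n_sets`` uniform subsets of size round(fraction·n_total) and
    intersects them.  Also reports the exceedance fraction of non-empty
    overlaps, an extension beyond the analytic expectation.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    size = int(round(fraction * n_total))
    counts = np.empty(n_reps)
    for r in range(n_reps):
        # membership-count trick: a CGI is in the intersection iff drawn n_sets times
        hits = np.zeros(n_total, dtype=np.int64)
        for _ in range(n_sets):
            hits[rng.choice(n_total, size=size, replace=False)] += 1
        counts[r] = np.count_nonzero(hits == n_sets)
    mean = float(counts.mean())
    se = float(counts.std(ddof=1) / np.sqrt(n_reps)) if n_reps > 1 else float("nan")
    return {
        "mean": mean,
        "se": se,
        "n_reps": n_reps,
        "p_nonempty": float((counts > 0).mean()),
    }


def pan_cancer_call(
    matrices: dict[str, CgiBetaMatrix], common_cgis, tissue_label: str = "pan-cancer"
) -> CimpResults:
    """k=2 CIMP call on all samples pooled across tissues, restricted to the
    cross-cancer signature CGIs."""
    common = sorted(common_cgis)
    if not common:
        raise ValueError("no cross-cancer signature: common CGI set is empty")
    blocks = []
    for tissue, mat in matrices.items():
        missing = [c for c in common if c not in mat.beta.index]
        if missing:
            raise ValueError(f"common CGIs absent from {tissue}: {missing[:5]}")
        sub = mat.beta.loc[common].copy()
        sub.columns = [f"{tissue}:{s}" for s in sub.columns]
        blocks.append(sub)
    pooled = CgiBetaMatrix(beta=pd.concat(blocks, axis=1))
    variances = pooled.beta.var(axis=1, ddof=1)
    signature = CimpSignature(
        tissue=tissue_label,
        cgi_ids=common,
        variance_fraction=1.0,
        variances=variances.sort_values(ascending=False),
    )
    return call_cimp(pooled, signature, k=2)


def cross_tabulate(pooled_call: CimpResults, per_tissue_labels: dict[str, pd.Series]) -> pd.DataFrame:
    """Cross-tabulation of pooled pan-cancer labels vs per-tissue labels."""
    rows = []
    for tissue, labels in per_tissue_labels.items():
        pooled = pooled_call.labels[[f"{tissue}:{s}" for s in labels.index]]
        pooled.index = labels.index
        tab = pd.crosstab(labels, pooled)
        tab.index = pd.MultiIndex.from_product([[tissue], tab.index])
        rows.append(tab)
    return pd.concat(rows).fillna(0).astype(int)
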