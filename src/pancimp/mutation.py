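"""Per-gene mutation association with CIMP status and mutation burden.

For each gene, a 2×2 table of mutation status × CIMP status is tested with
the hypergeometric (one-sided Fisher) tail in both directions; p = 2·min of
the two tails (capped at 1), with the direction of enrichment reported.
Benjamini-Hochberg correction controls the FDR across tested genes.
Mutation burden (per-sample mutation counts) is compared between classes
with a two-sided Wilcoxon rank-sum test.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._labels import to_binary

CANDIDATE_GENES = ("IDH1", "IDH2", "BRAF", "KRAS", "TET2")


def hypergeom_enrichment(k: int, n_pos: int, n_mut: int, n_total: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(n_total, n_mut, n_pos).

    ``k`` mutated CIMP-positive samples out of ``n_pos`` positives, with
    ``n_mut`` mutated samples among ``n_total`` overall — the one-sided
    Fisher exact enrichment p-value.
    """
    if not (0 <= n_mut <= n_total and 0 <= n_pos <= n_total):
        raise ValueError("margins must satisfy n_pos, n_mut <= n_total")
    if k > min(n_pos, n_mut) or k < 0:
        raise ValueError("k must satisfy 0 <= k <= min(n_pos, n_mut)")
    return float(stats.hypergeom.sf(k - 1, n_total, n_mut, n_pos))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class AssociationResult:
    """One gene's mutation × CIMP association."""

    gene: str
    n_mut_pos: int
    n_mut_neg: int
    n_pos: int
    n_neg: int
    direction: str  # enrichment in "positive" or "negative"
    p_value: float
    q_value: float = np.nan


def _two_sided_gene_p(k_pos, n_pos, n_mut, n_total):
    p_pos = hypergeom_enrichment(k_pos, n_pos, n_mut, n_total)
    k_neg = n_mut - k_pos
    p_neg = hypergeom_enrichment(k_neg, n_total - n_pos, n_mut, n_total)
    if p_pos <= p_neg:
        return min(1.0, 2.0 * p_pos), "positive"
    return min(1.0, 2.0 * p_neg), "negative"


def genomewide_mutation_scan(
    mutations: pd.DataFrame, labels: pd.Series, min_mutated: int = 3
) -> pd.DataFrame:
    """Two-sided hypergeometric scan over all genes with >= ``min_mutated``
    mutated samples, BH-corrected, sorted by q.

    ``mutations`` is a binary gene × sample matrix; ``labels`` a CIMP call
    over (a superset of) the same samples.
    """
    common = mutations.columns.intersection(labels.index)
    if len(common) == 0:
        raise ValueError("no sample overlap between mutations and CIMP call")
    mut = mutations[common]
    y = to_binary(labels.loc[common])
    n_total = len(common)
    n_pos = int(y.sum())
    n_mut_per_gene = mut.sum(axis=1)
    tested = n_mut_per_gene[n_mut_per_gene >= min_mutated].index
    if len(tested) == 0:
        warnings.warn("no gene reaches the min_mutated threshold")
        return pd.DataFrame(
            columns=["gene", "n_mut_pos", "n_mut_neg", "n_pos", "n_neg",
                     "direction", "p", "q"]
        ).set_index("gene")
    k_pos_all = mut.loc[tested] @ y
    rows = []
    for gene in tested:
        n_mut = int(n_mut_per_gene[gene])
        k_pos = int(k_pos_all[gene])
        p, direction = _two_sided_gene_p(k_pos, n_pos, n_mut, n_total)
        rows.append((gene, k_pos, n_mut - k_pos, n_pos, n_total - n_pos, direction, p))
    out = pd.DataFrame(
        rows, columns=["gene", "n_mut_pos", "n_mut_neg", "n_pos", "n_neg",
                       "direction", "p"]
    ).set_index("gene")
    out["q"] = benjamini_hochberg(out["p"].to_numpy())
    return out.sort_values(["q", "p", "gene"], kind="mergesort")


def burden_comparison(mutations: pd.DataFrame, labels: pd.Series) -> dict:
    """Wilcoxon rank-sum comparison of per-sample mutation counts by class."""
    common = mutations.columns.intersection(labels.index)
    y = to_binary(labels.loc[common])
    counts = mutations[common].sum(axis=0)
    pos, neg = counts[y == 1], counts[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both CIMP classes must be present")
    if pos.nunique() == 1 and neg.nunique() == 1 and pos.iloc[0] == neg.iloc[0]:
        stat, p = 0.0, 1.0  # fully tied: no evidence either way
    else:
        res = stats.mannwhitneyu(pos, neg, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "median_positive": float(pos.median()),
        "median_negative": float(neg.median()),
        "n_positive": int(len(pos)),
        "n_negative": int(len(neg)),
        "statistic": stat,
        "p_value": p,
    }


def candidate_gene_table(
    mutations_by_tissue: dict[str, pd.DataFrame],
    labels_by_tissue: dict[str, pd.Series],
    genes=CANDIDATE_GENES,
) -> pd.DataFrame:
    """Per-candidate-gene, per-tissue mutation × CIMP association summary.

    Genes absent from a tissue's matrix are flagged and not tested; BH
    correction is applied across the tested (gene, tissue) cells.
    """
    rows = []
    for tissue, mut in mutations_by_tissue.items():
        labels = labels_by_tissue[tissue]
        common = mut.columns.intersection(labels.index)
        y = to_binary(labels.loc[common])
        n_total, n_pos = len(common), int(y.sum())
        for gene in genes:
            if gene not in mut.index:
                rows.append((gene, tissue, "absent", 0, 0, n_pos,
                             n_total - n_pos, np.nan, np.nan))
                continue
            vec = mut.loc[gene, common]
            n_mut = int(vec.sum())
            k_pos = int((vec * y).sum())
            if n_mut == 0:
                rows.append((gene, tissue, "no_mutations", 0, 0, n_pos,
                             n_total - n_pos, 1.0, np.nan))
                continue
            p, direction = _two_sided_gene_p(k_pos, n_pos, n_mut, n_total)
            rows.append((gene, tissue, direction, k_pos, n_mut - k_pos,
                         n_pos, n_total - n_pos, p, np.nan))
    out = pd.DataFrame(
        rows, columns=["gene", "tissue", "status", "n_mut_pos", "n_mut_neg",
                       "n_pos", "n_neg", "p", "q"]
    )
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = benjamini_hochberg(out.loc[tested, "p"].to_numpy())
    return out.set_index(["gene", "tissue"])


def maf_to_binary_matrix(
    maf: pd.DataFrame,
    gene_col: str = "Hugo_Symbol",
    sample_col: str = "Tumor_Sample_Barcode",
    class_col: str = "Variant_Classification",
    silent_classes=("Silent",),
) -> pd.DataFrame:
    """Collapse a minimal MAF table to a binary gene × sample matrix.

    Any variant whose classification is not in ``silent_classes`` marks the
    gene as mutated in that sample.
    """
    keep = ~maf[class_col].isin(silent_classes)
    sub = maf.loc[keep, [gene_col, sample_col]].drop_duplicates()
    mat = pd.crosstab(sub[gene_col], sub[sample_col]).clip(upper=1)
    return mat.rename_axis(index="gene_id", columns=None)
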