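"""Mutation association: hypergeometric tail, BH correction, scans, burden."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pancimp.mutation import (
    benjamini_hochberg,
    burden_comparison,
    candidate_gene_table,
    genomewide_mutation_scan,
    hypergeom_enrichment,
    maf_to_binary_matrix,
)


def _brute_force_hypergeom_tail(k, n_pos, n_mut, n_total):
    """Oracle: enumerate the hypergeometric pmf and sum the upper tail."""
    def pmf(x):
        return (
            math.comb(n_mut, x) * math.comb(n_total - n_mut, n_pos - x)
            / math.comb(n_total, n_pos)
        )
    return sum(pmf(x) for x in range(k, min(n_pos, n_mut) + 1))


def _brute_force_bh(p):
    """Oracle: literal step-up definition q_i = min_{j>=i} (m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1]
    )[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestHypergeomEnrichment:
    def test_zero_count_is_one(self):
        assert hypergeom_enrichment(0, 10, 6, 20) == pytest.approx(1.0)

    def test_forced_outcome_is_one(self):
        assert hypergeom_enrichment(5, 5, 5, 5) == pytest.approx(1.0)

    def test_specific_table_matches_enumeration(self):
        got = hypergeom_enrichment(5, 10, 6, 20)
        assert got == pytest.approx(_brute_force_hypergeom_tail(5, 10, 6, 20),
                                    abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.data())
    def test_matches_enumeration_on_all_small_tables(self, data):
        n_total = data.draw(st.integers(1, 25))
        n_pos = data.draw(st.integers(0, n_total))
        n_mut = data.draw(st.integers(0, n_total))
        k = data.draw(st.integers(0, min(n_pos, n_mut)))
        got = hypergeom_enrichment(k, n_pos, n_mut, n_total)
        assert got == pytest.approx(
            _brute_force_hypergeom_tail(k, n_pos, n_mut, n_total), abs=1e-12
        )

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(3, 30, 5, 20)
        with pytest.raises(ValueError):
            hypergeom_enrichment(6, 10, 5, 20)


class TestBenjaminiHochberg:
    def test_equal_ps_unchanged(self):
        q = benjamini_hochberg([0.07, 0.07, 0.07])
        assert np.allclose(q, 0.07)

    def test_hand_computed_step_up(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, ps):
        assert np.allclose(benjamini_hochberg(ps), _brute_force_bh(ps), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


def _mutation_frame(rng, n_genes, n_samples, p=0.05):
    return pd.DataFrame(
        (rng.random((n_genes, n_samples)) < p).astype(int),
        index=[f"G{i:04d}" for i in range(n_genes)],
        columns=[f"s{i}" for i in range(n_samples)],
    )


def _labels(n_samples, n_pos, name_prefix="s"):
    lab = ["positive"] * n_pos + ["negative"] * (n_samples - n_pos)
    return pd.Series(lab, index=[f"{name_prefix}{i}" for i in range(n_samples)])


class TestGenomewideScan:
    def test_min_mutated_filter(self):
        rng = np.random.default_rng(0)
        mut = _mutation_frame(rng, 5, 30, p=0.0)
        mut.iloc[0, :2] = 1  # two mutated samples only
        mut.iloc[1, :5] = 1
        scan = genomewide_mutation_scan(mut, _labels(30, 10), min_mutated=3)
        assert "G0000" not in scan.index and "G0001" in scan.index

    def test_planted_association_ranks_first(self):
        rng = np.random.default_rng(1)
        mut = _mutation_frame(rng, 300, 200, p=0.03)
        labels = _labels(200, 70)
        planted = "G0000"
        mut.loc[planted] = 0
        mut.loc[planted, labels.index[labels == "positive"][:30]] = 1
        scan = genomewide_mutation_scan(mut, labels)
        assert scan.index[0] == planted
        assert scan.loc[planted, "direction"] == "positive"

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(2)
        mut = _mutation_frame(rng, 40, 60)
        labels = _labels(60, 20)
        a = genomewide_mutation_scan(mut, labels)
        b = genomewide_mutation_scan(mut.sample(frac=1, random_state=3), labels)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_empty_result_warns(self):
        mut = _mutation_frame(np.random.default_rng(3), 5, 20, p=0.0)
        with pytest.warns(UserWarning, match="min_mutated"):
            scan = genomewide_mutation_scan(mut, _labels(20, 8))
        assert scan.empty

    def test_no_overlap_rejected(self):
        mut = _mutation_frame(np.random.default_rng(4), 5, 10)
        labels = _labels(10, 4, name_prefix="other")
        with pytest.raises(ValueError, match="overlap"):
            genomewide_mutation_scan(mut, labels)


class TestBurdenComparison:
    def test_equal_distributions_not_significant(self):
        """Type-I behaviour: identical count distributions rarely reject."""
        rng = np.random.default_rng(5)
        rejections = 0
        n_reps = 50
        for _ in range(n_reps):
            counts = rng.poisson(10, size=80)
            mut = pd.DataFrame(
                np.zeros((1, 80), dtype=int),
                index=["G"], columns=[f"s{i}" for i in range(80)],
            )
            # encode counts through a stack of pseudo-genes
            mut = pd.DataFrame(
                (np.arange(40)[:, None] < counts[None, :]).astype(int),
                index=[f"G{i}" for i in range(40)],
                columns=[f"s{i}" for i in range(80)],
            )
            out = burden_comparison(mut, _labels(80, 40))
            rejections += out["p_value"] < 0.05
        assert rejections / n_reps <= 0.07 + 3 * np.sqrt(0.05 * 0.95 / n_reps)

    def test_planted_burden_detected(self):
        rng = np.random.default_rng(6)
        n = 200
        counts = np.r_[rng.poisson(30, n // 2), rng.poisson(10, n // 2)]
        mut = pd.DataFrame(
            (np.arange(80)[:, None] < counts[None, :]).astype(int),
            index=[f"G{i}" for i in range(80)],
            columns=[f"s{i}" for i in range(n)],
        )
        out = burden_comparison(mut, _labels(n, n // 2))
        assert out["p_value"] < 1e-3
        assert out["median_positive"] > out["median_negative"]

    def test_fully_tied_counts_handled(self):
        mut = pd.DataFrame(
            np.ones((3, 10), dtype=int),
            index=["a", "b", "c"], columns=[f"s{i}" for i in range(10)],
        )
        out = burden_comparison(mut, _labels(10, 5))
        assert out["p_value"] == pytest.approx(1.0)

    def test_single_class_rejected(self):
        mut = _mutation_frame(np.random.default_rng(7), 5, 10)
        with pytest.raises(ValueError, match="both CIMP classes"):
            burden_comparison(mut, _labels(10, 0))


class TestCandidateGeneTable:
    def test_absent_gene_flagged(self):
        rng = np.random.default_rng(8)
        mut = _mutation_frame(rng, 10, 30)
        mut.index = [f"G{i:04d}" for i in range(10)]
        table = candidate_gene_table({"t1": mut}, {"t1": _labels(30, 10)},
                                     genes=("BRAF", "G0001"))
        assert table.loc[("BRAF", "t1"), "status"] == "absent"
        assert np.isnan(table.loc[("BRAF", "t1"), "p"])

    def test_all_zero_gene_p_is_one(self):
        mut = _mutation_frame(np.random.default_rng(9), 3, 20, p=0.0)
        mut.index = ["BRAF", "KRAS", "IDH1"]
        table = candidate_gene_table({"t1": mut}, {"t1": _labels(20, 8)},
                                     genes=("BRAF",))
        assert table.loc[("BRAF", "t1"), "status"] == "no_mutations"
        assert table.loc[("BRAF", "t1"), "p"] == pytest.approx(1.0)

    def test_tissue_specific_association(self):
        """A BRAF-like planted association shows up only in its tissue."""
        rng = np.random.default_rng(10)
        tissues, labels = {}, {}
        for t, planted in [("colon", True), ("lung", False)]:
            mut = _mutation_frame(rng, 5, 120, p=0.02)
            mut.index = ["BRAF", "KRAS", "IDH1", "IDH2", "TET2"]
            lab = _labels(120, 40)
            if planted:
                mut.loc["BRAF"] = 0
                mut.loc["BRAF", lab.index[lab == "positive"][:25]] = 1
            tissues[t], labels[t] = mut, lab
        table = candidate_gene_table(tissues, labels)
        assert table.loc[("BRAF", "colon"), "q"] < 0.05
        assert table.loc[("BRAF", "lung"), "q"] > 0.05


def test_maf_collapse_counts_non_silent_only():
    maf = pd.DataFrame(
        {
            "Hugo_Symbol": ["BRAF", "BRAF", "KRAS", "KRAS"],
            "Tumor_Sample_Barcode": ["s1", "s2", "s1", "s1"],
            "Variant_Classification": [
                "Missense_Mutation", "Silent", "Nonsense_Mutation",
                "Missense_Mutation",
            ],
        }
    )
    mat = maf_to_binary_matrix(maf)
    assert mat.loc["BRAF", "s1"] == 1
    assert "s2" not in mat.columns or mat.loc["BRAF", "s2"] == 0
    assert mat.loc["KRAS", "s1"] == 1  # deduplicated to binary
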