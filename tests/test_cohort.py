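"""Cohort summary tables and the two-proportion chi-square comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2 as chi2_dist

from tp53hgsoc.cohort import (
    compare_to_reference,
    compare_truncating_to_reference,
    summarize_cohort,
    tabulate_other_genes,
    two_proportion_chi2,
)
from tp53hgsoc.types import ReferenceCohort

REFERENCE = ReferenceCohort(
    n_cases=1249, counts={"GOF": 271, "LOF": 261, "unclassified": 717})


def brute_force_chi2(x1, n1, x2, n2, yates=False):
    """Independent 2×2 oracle: explicit expected-count formula."""
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0)
    stat = float((diff ** 2 / expected).sum())
    return stat, float(chi2_dist.sf(stat, 1))


class TestChi2:
    @given(st.integers(1, 80), st.integers(81, 200),
           st.integers(1, 800), st.integers(801, 2000))
    def test_equals_brute_force_oracle(self, x1, n1, x2, n2):
        res = two_proportion_chi2(x1, n1, x2, n2)
        stat, p = brute_force_chi2(x1, n1, x2, n2)
        stat_y, p_y = brute_force_chi2(x1, n1, x2, n2, yates=True)
        assert res.statistic == pytest.approx(stat, abs=1e-9)
        assert res.p_uncorrected == pytest.approx(p, abs=1e-9)
        assert res.statistic_yates == pytest.approx(stat_y, abs=1e-9)
        assert res.p_yates == pytest.approx(p_y, abs=1e-9)

    def test_truncating_comparison_value(self):
        """30/99 vs 261/1249: uncorrected two-sided p ≈ 0.029."""
        res = two_proportion_chi2(30, 99, 261, 1249)
        assert res.p_uncorrected == pytest.approx(0.0285, abs=5e-4)
        assert res.prop_cohort == pytest.approx(30 / 99)
        assert res.prop_reference == pytest.approx(0.209, abs=5e-4)

    def test_identical_proportions_give_p_one(self):
        res = two_proportion_chi2(30, 99, 30, 99)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_uncorrected == pytest.approx(1.0)

    def test_small_expected_counts_warn(self):
        res = two_proportion_chi2(1, 3, 1, 1000)
        assert res.warning is not None

    def test_reference_lof_proportion(self):
        assert REFERENCE.proportion("LOF") == pytest.approx(0.209, abs=5e-4)
        assert round(100 * REFERENCE.proportion("LOF")) == 21


class TestSummarize:
    def test_published_type_counts(self, table1_cohort):
        classified, meta = table1_cohort
        s = summarize_cohort(classified, meta)
        assert s.n_patients == 99
        assert s.n_tp53_mutant == 95
        assert s.type_counts.loc["missense", "total"] == 58
        assert s.type_counts.loc["frameshift", "total"] == 15
        assert s.type_counts.loc["nonsense", "total"] == 15
        assert s.type_counts.loc["other", "total"] == 7
        assert s.category_counts.loc["LOF", "total"] == 30
        assert s.truncating_count == 30
        assert s.truncating_pct_of_patients == pytest.approx(30.3, abs=0.05)

    def test_both_denominators_reported(self, table1_cohort):
        classified, meta = table1_cohort
        s = summarize_cohort(classified, meta)
        assert s.pct_of_patients.loc["LOF", "total"] == pytest.approx(100 * 30 / 99)
        assert s.pct_of_mutant.loc["LOF", "total"] == pytest.approx(100 * 30 / 95)

    def test_comparison_against_reference(self, table1_cohort):
        classified, meta = table1_cohort
        s = summarize_cohort(classified, meta)
        res = compare_truncating_to_reference(s, REFERENCE)
        assert res.counts == (30, 99, 261, 1249)
        assert res.p_uncorrected == pytest.approx(0.0285, abs=5e-4)
        res_lof = compare_to_reference(s, REFERENCE, "LOF")
        assert res_lof.counts[0] == 30

    def test_multi_variant_patient_counted_once_by_severity(self):
        classified = pd.DataFrame([
            {"sample_id": "S1", "consequence": "missense",
             "category": "GOF"},
            {"sample_id": "S1", "consequence": "nonsense",
             "category": "LOF"},
        ])
        meta = pd.DataFrame([{"sample_id": "S1", "tumor_cell_pct": 60,
                              "brca_gene": "BRCA1"}])
        s = summarize_cohort(classified, meta)
        assert s.n_tp53_variants == 2
        assert s.n_tp53_mutant == 1
        # patient-level: once, under LOF (LOF > GOF > unclassified)
        assert s.patient_category_counts.loc["LOF", "total"] == 1
        assert s.patient_category_counts["total"].sum() == 1
        # variant-level: both counted
        assert s.category_counts["total"].sum() == 2

    def test_empty_cohort_all_zero(self):
        classified = pd.DataFrame(
            columns=["sample_id", "consequence", "category"])
        meta = pd.DataFrame([{"sample_id": "S1", "tumor_cell_pct": 60,
                              "brca_gene": "BRCA1"}])
        s = summarize_cohort(classified, meta)
        assert s.n_tp53_variants == 0
        assert (s.type_counts["total"] == 0).all()

    def test_percentages_recompute_from_counts(self, table1_cohort):
        classified, meta = table1_cohort
        s = summarize_cohort(classified, meta)
        for cat in ("GOF", "LOF", "unclassified"):
            assert s.pct_of_patients.loc[cat, "total"] == pytest.approx(
                100 * s.category_counts.loc[cat, "total"] / s.n_patients)


class TestOtherGenes:
    def test_nine_variants_across_five_genes(self):
        genes = (["APC"] + ["BAX"] + ["KRAS"] + ["CDKN2A"] * 4
                 + ["CTNNB1"] * 2)
        rows = [{"sample_id": f"S{i}", "gene": g, "chrom": "chr1",
                 "pos": i + 1, "ref": "C", "alt": "T"}
                for i, g in enumerate(genes)]
        non_tp53 = pd.DataFrame(rows)
        loh = pd.DataFrame([{
            "sample_id": "S2", "chrom": "chr1", "pos": 3, "ref": "C",
            "alt": "T", "norm_vaf": 0.23, "status": "subclonal_variant"}])
        table = tabulate_other_genes(non_tp53, loh)
        assert len(table) == 9
        assert table["gene"].nunique() == 5
        counts = table.groupby("gene")["n_in_gene"].first().to_dict()
        assert counts == {"APC": 1, "BAX": 1, "KRAS": 1, "CDKN2A": 4,
                          "CTNNB1": 2}
        kras = table[table["gene"] == "KRAS"].iloc[0]
        assert kras["status"] == "subclonal_variant"
        assert kras["norm_vaf"] == pytest.approx(0.23)

    def test_empty_table(self):
        table = tabulate_other_genes(
            pd.DataFrame(columns=["sample_id", "gene", "chrom", "pos",
                                  "ref", "alt"]),
            pd.DataFrame())
        assert table.empty
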