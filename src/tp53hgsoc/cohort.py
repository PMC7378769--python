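"""Cohort frequency tables and comparison against a reference variant set.

Builds per-cohort counts of TP53 mutation types (missense / frameshift /
nonsense / other) and functional categories (GOF / LOF / unclassified),
stratified by BRCA carrier gene, and compares a category's frequency
against a reference cohort with a two-proportion chi-square test on the
2×2 contingency table. Category percentages are reported under both
denominators in circulation — all patients, and TP53-mutant patients —
each clearly labelled, since published summaries mix them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .types import Category, ReferenceCohort

#: Consequence → mutation-type bucket used in the frequency tables.
TYPE_BUCKETS = {
    "missense": "missense",
    "frameshift": "frameshift",
    "nonsense": "nonsense",
}
MUTATION_TYPES = ("missense", "frameshift", "nonsense", "other")
TRUNCATING_TYPES = ("frameshift", "nonsense")

#: Sample-level category precedence for patient tallies: a patient with two
#: TP53 variants counts once, under the more function-damaging category.
PATIENT_CATEGORY_PRECEDENCE = ("LOF", "GOF", "unclassified")


def mutation_type(consequence: str) -> str:
    return TYPE_BUCKETS.get(consequence, "other")


@dataclass
class Chi2Result:
    statistic: float
    df: int
    p_uncorrected: float
    statistic_yates: float
    p_yates: float
    prop_cohort: float
    prop_reference: float
    counts: tuple[int, int, int, int]   # (x1, n1, x2, n2)
    warning: str | None = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic, "df": self.df,
            "p_uncorrected": self.p_uncorrected,
            "statistic_yates": self.statistic_yates, "p_yates": self.p_yates,
            "prop_cohort": self.prop_cohort,
            "prop_reference": self.prop_reference,
            "counts": list(self.counts), "warning": self.warning,
        }


@dataclass
class CohortSummary:
    """Per-cohort counts and frequencies (variant- and patient-level)."""

    n_patients: int
    n_tp53_mutant: int
    n_tp53_variants: int
    type_counts: pd.DataFrame        # rows: mutation types, cols: BRCA strata + total
    category_counts: pd.DataFrame    # rows: categories, cols: BRCA strata + total
    patient_category_counts: pd.DataFrame  # patient-level (one count per patient)
    pct_of_patients: pd.DataFrame    # category % with all-patients denominator
    pct_of_mutant: pd.DataFrame      # category % with TP53-mutant denominator
    truncating_count: int = 0
    truncating_pct_of_patients: float = float("nan")
    comparisons: dict[str, Chi2Result] = field(default_factory=dict)


def summarize_cohort(classified: pd.DataFrame, meta: pd.DataFrame) -> CohortSummary:
    """Tabulate TP53 variant types and categories for a cohort.

    ``classified`` is the per-variant frame (columns sample_id,
    consequence, category); ``meta`` has sample_id and brca_gene for every
    enrolled patient (defining the all-patients denominator). Patients
    carrying two TP53 variants contribute every variant to variant-level
    tallies but are counted once, under the more severe category, in
    patient-level tallies.
    """
    meta = meta.copy()
    meta["sample_id"] = meta["sample_id"].astype(str)
    strata = [g for g in ("BRCA1", "BRCA2", "none")
              if (meta["brca_gene"] == g).any()]
    n_patients = meta["sample_id"].nunique()

    df = classified.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.merge(meta[["sample_id", "brca_gene"]], on="sample_id", how="left")
    df["brca_gene"] = df["brca_gene"].fillna("none")
    df["mutation_type"] = df["consequence"].map(mutation_type)

    def _counts(frame: pd.DataFrame, col: str, index: tuple[str, ...]) -> pd.DataFrame:
        out = pd.DataFrame(0, index=list(index), columns=strata + ["total"])
        for stratum in strata:
            vc = frame.loc[frame["brca_gene"] == stratum, col].value_counts()
            for name in index:
                out.loc[name, stratum] = int(vc.get(name, 0))
        out["total"] = out[strata].sum(axis=1)
        return out

    categories = tuple(c.value for c in Category)
    type_counts = _counts(df, "mutation_type", MUTATION_TYPES)
    category_counts = _counts(df, "category", categories)

    # Patient-level: one row per patient, category by precedence.
    def _collapse(cats: pd.Series) -> str:
        for cat in PATIENT_CATEGORY_PRECEDENCE:
            if (cats == cat).any():
                return cat
        return str(cats.iloc[0])

    per_patient = (df.groupby(["sample_id", "brca_gene"])["category"]
                     .apply(_collapse).reset_index())
    patient_category_counts = _counts(per_patient, "category", categories)

    n_mutant_by_stratum = {
        s: int(per_patient.loc[per_patient["brca_gene"] == s, "sample_id"].nunique())
        for s in strata
    }
    n_tp53_mutant = int(per_patient["sample_id"].nunique())
    n_patients_by_stratum = {
        s: int((meta["brca_gene"] == s).sum()) for s in strata
    }

    def _pct(counts: pd.DataFrame, denoms: dict[str, int], total_denom: int) -> pd.DataFrame:
        pct = counts.astype(float).copy()
        for s in strata:
            pct[s] = np.where(denoms[s] > 0, 100.0 * counts[s] / max(denoms[s], 1),
                              np.nan)
        pct["total"] = 100.0 * counts["total"] / total_denom if total_denom else np.nan
        return pct

    pct_of_patients = _pct(category_counts, n_patients_by_stratum, n_patients)
    pct_of_mutant = _pct(category_counts, n_mutant_by_stratum, n_tp53_mutant)

    truncating = int(type_counts.loc[list(TRUNCATING_TYPES), "total"].sum())
    return CohortSummary(
        n_patients=n_patients,
        n_tp53_mutant=n_tp53_mutant,
        n_tp53_variants=len(df),
        type_counts=type_counts,
        category_counts=category_counts,
        patient_category_counts=patient_category_counts,
        pct_of_patients=pct_of_patients,
        pct_of_mutant=pct_of_mutant,
        truncating_count=truncating,
        truncating_pct_of_patients=(100.0 * truncating / n_patients
                                    if n_patients else float("nan")),
    )


def two_proportion_chi2(x1: int, n1: int, x2: int, n2: int) -> Chi2Result:
    """Chi-square test for equality of two proportions (x1/n1 vs x2/n2).

    Reports both the uncorrected statistic (default) and the
    Yates-corrected one. Warns when an expected cell count falls below 1,
    where an exact test is preferable.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    obs = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    warning = None
    if obs.sum(axis=1).min() > 0 and obs.sum(axis=0).min() > 0:
        expected = stats.contingency.expected_freq(obs)
        if expected.min() < 1:
            warning = "expected cell count < 1; consider Fisher's exact test"
        plain = stats.chi2_contingency(obs, correction=False)
        yates = stats.chi2_contingency(obs, correction=True)
        stat, p = float(plain.statistic), float(plain.pvalue)
        stat_y, p_y = float(yates.statistic), float(yates.pvalue)
    else:
        # Degenerate margin: no variation to test.
        stat = stat_y = 0.0
        p = p_y = 1.0
        warning = "degenerate 2x2 margin; test not informative"
    return Chi2Result(
        statistic=stat, df=1, p_uncorrected=p,
        statistic_yates=stat_y, p_yates=p_y,
        prop_cohort=x1 / n1, prop_reference=x2 / n2,
        counts=(x1, n1, x2, n2), warning=warning,
    )


def compare_to_reference(
    summary: CohortSummary,
    reference: ReferenceCohort,
    category: str,
    denominator: str = "patients",
) -> Chi2Result:
    """Compare one category's cohort frequency against the reference set.

    ``denominator`` selects the cohort denominator: "patients" (all
    enrolled patients) or "tp53_mutant" (patients with a TP53 variant).
    The cohort numerator is the patient-level category count.
    """
    x1 = int(summary.patient_category_counts.loc[category, "total"])
    n1 = summary.n_patients if denominator == "patients" else summary.n_tp53_mutant
    result = two_proportion_chi2(x1, n1, reference.counts[category],
                                 reference.n_cases)
    summary.comparisons[f"{category}|{denominator}"] = result
    return result


def compare_truncating_to_reference(
    summary: CohortSummary, reference: ReferenceCohort,
    reference_category: str = "LOF",
) -> Chi2Result:
    """Compare the truncating-variant (frameshift + nonsense) frequency,
    all-patients denominator, against the reference LOF counts."""
    result = two_proportion_chi2(
        summary.truncating_count, summary.n_patients,
        reference.counts[reference_category], reference.n_cases,
    )
    summary.comparisons[f"truncating|patients"] = result
    return result


def tabulate_other_genes(
    classified_non_tp53: pd.DataFrame,
    loh_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant table of concomitant non-TP53 oncogene calls with their
    clonality status, plus per-gene counts in the ``n_in_gene`` column.

    ``classified_non_tp53`` needs sample_id/gene/chrom/pos/ref/alt (and
    optionally consequence/protein_change); ``loh_calls`` is the LOH frame
    keyed the same way.
    """
    cols = ["gene", "sample_id", "chrom", "pos", "ref", "alt",
            "consequence", "protein_change", "norm_vaf", "status", "n_in_gene"]
    if classified_non_tp53.empty:
        return pd.DataFrame(columns=cols)
    df = classified_non_tp53.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    if not loh_calls.empty:
        df = df.merge(
            loh_calls[["sample_id", "chrom", "pos", "ref", "alt",
                       "norm_vaf", "status"]],
            on=["sample_id", "chrom", "pos", "ref", "alt"], how="left")
    else:
        df["norm_vaf"] = np.nan
        df["status"] = None
    for c in ("consequence", "protein_change"):
        if c not in df.columns:
            df[c] = ""
    df["n_in_gene"] = df.groupby("gene")["gene"].transform("size")
    return (df[cols].sort_values(["gene", "sample_id", "pos"])
              .reset_index(drop=True))
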