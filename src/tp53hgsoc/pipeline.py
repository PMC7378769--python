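"""End-to-end orchestration: ingest → filter → classify → LOH → IHC →
cohort summary → report files."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as tio
from .classify import classified_to_frame, classify_cohort
from .cohort import (
    CohortSummary,
    compare_to_reference,
    compare_truncating_to_reference,
    summarize_cohort,
    tabulate_other_genes,
)
from .filtering import FilterParams, FilterResult, filter_somatic
from .ihc import concordance_table, lof_predictive_metrics
from .loh import (
    BandParams,
    infer_loh,
    loh_rate_by_category,
    loh_to_frame,
    sample_loh_status,
)
from .types import ReferenceCohort, SampleMeta

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    filter_result: FilterResult
    classified_df: pd.DataFrame          # TP53 variants
    non_tp53_df: pd.DataFrame
    loh_df: pd.DataFrame
    loh_rates: pd.DataFrame
    sample_loh: pd.DataFrame
    summary: CohortSummary | None
    contingency: pd.DataFrame | None
    ihc_metrics: dict | None
    other_genes: pd.DataFrame
    report: dict = field(default_factory=dict)


def run_pipeline(
    tumor_path: str | Path,
    normal_path: str | Path | None,
    meta_path: str | Path,
    *,
    gof_list_path: str | Path | None = None,
    annotations_path: str | Path | None = None,
    reference_path: str | Path | None = None,
    filter_params: FilterParams | None = None,
    bands: BandParams | None = None,
    allow_missing_normal: bool = False,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the full analysis from input files; optionally write reports."""
    filter_params = filter_params or FilterParams()
    bands = bands or BandParams()

    tumor_calls = tio.read_variant_calls(tumor_path, "tumor")
    if normal_path is not None:
        normal_calls = tio.read_variant_calls(normal_path, "normal")
        normal_samples = (set(tio.vcf_sample_ids(normal_path))
                          if str(normal_path).endswith(".vcf")
                          else None)
    else:
        normal_calls, normal_samples = [], set()
        allow_missing_normal = True
    meta, meta_rejects = tio.read_sample_meta(meta_path)
    meta_by_id = {m.sample_id: m for m in meta}

    fres = filter_somatic(tumor_calls, normal_calls, filter_params,
                          normal_samples=normal_samples,
                          allow_missing_normal=allow_missing_normal)

    kept = [c for c in fres.kept if c.sample_id in meta_by_id]
    dropped_no_meta = len(fres.kept) - len(kept)
    if dropped_no_meta:
        logger.warning("%d kept calls dropped for missing sample metadata",
                       dropped_no_meta)

    gof_list = tio.read_gof_list(gof_list_path)
    iarc = (tio.read_iarc_annotations(annotations_path)
            if annotations_path else None)

    tp53_calls = [c for c in kept if c.gene == "TP53"]
    other_calls = [c for c in kept if c.gene != "TP53"]
    classified = classify_cohort(tp53_calls, gof_list, iarc)
    classified_df = classified_to_frame(classified)

    non_tp53_df = pd.DataFrame([{
        "sample_id": c.sample_id, "gene": c.gene, "chrom": c.chrom,
        "pos": c.pos, "ref": c.ref, "alt": c.alt,
        "consequence": c.consequence.value,
        "protein_change": c.protein_change, "vaf": c.vaf,
    } for c in other_calls], columns=["sample_id", "gene", "chrom", "pos",
                                      "ref", "alt", "consequence",
                                      "protein_change", "vaf"])

    loh_calls = infer_loh(kept, meta_by_id, bands)
    loh_df = loh_to_frame(loh_calls)
    tp53_loh = [c for c, call in zip(loh_calls, kept) if call.gene == "TP53"]
    loh_rates = loh_rate_by_category(tp53_loh, classified)
    sample_loh = sample_loh_status(tp53_loh)

    meta_df = pd.DataFrame([{
        "sample_id": m.sample_id, "tumor_cell_pct": m.tumor_cell_pct,
        "brca_gene": m.brca_gene.value,
        "ihc_pct_positive": m.ihc_pct_positive,
    } for m in meta])

    summary = summarize_cohort(classified_df, meta_df) if len(meta_df) else None

    reference: ReferenceCohort | None = None
    if reference_path is not None:
        reference = tio.read_reference_counts(reference_path)
    if summary is not None and reference is not None:
        for cat in ("GOF", "LOF", "unclassified"):
            if cat in reference.counts:
                compare_to_reference(summary, reference, cat)
        if "LOF" in reference.counts:
            compare_truncating_to_reference(summary, reference)

    # IHC concordance over samples with a measurement.
    contingency = None
    ihc_metrics = None
    ihc_df = meta_df.dropna(subset=["ihc_pct_positive"]).rename(
        columns={"ihc_pct_positive": "pct_positive"})
    if len(ihc_df):
        tp53_mutant = set(classified_df["sample_id"].astype(str))
        wild_type = set(meta_df["sample_id"].astype(str)) - tp53_mutant
        contingency = concordance_table(ihc_df, classified_df,
                                        wild_type_samples=wild_type)
        m = lof_predictive_metrics(contingency)
        ihc_metrics = {
            "sensitivity": m.sensitivity,
            "specificity_gof": m.specificity_gof,
            "specificity_non_lof": m.specificity_non_lof,
            "n_lof": m.n_lof, "n_gof": m.n_gof, "n_non_lof": m.n_non_lof,
        }

    other_genes = tabulate_other_genes(non_tp53_df, loh_df)

    report = _build_report(fres, classified_df, loh_df, loh_rates, sample_loh,
                           summary, contingency, ihc_metrics, other_genes)
    result = PipelineResult(
        filter_result=fres, classified_df=classified_df,
        non_tp53_df=non_tp53_df, loh_df=loh_df, loh_rates=loh_rates,
        sample_loh=sample_loh, summary=summary, contingency=contingency,
        ihc_metrics=ihc_metrics, other_genes=other_genes, report=report,
    )
    if out_dir is not None:
        write_outputs(result, out_dir)
    return result


def _build_report(fres, classified_df, loh_df, loh_rates, sample_loh,
                  summary, contingency, ihc_metrics, other_genes) -> dict:
    from collections import Counter
    reasons = Counter(r.reason for r in fres.rejected)
    report: dict = {
        "n_input_calls": fres.n_input,
        "n_kept": len(fres.kept),
        "n_rejected": len(fres.rejected),
        "rejection_reasons": dict(sorted(reasons.items())),
        "category_counts": (classified_df["category"].value_counts()
                            .sort_index().to_dict()),
        "loh_status_counts": (loh_df["status"].value_counts()
                              .sort_index().to_dict() if len(loh_df) else {}),
        "n_samples_loh_positive": int(sample_loh["loh_positive"].sum())
        if len(sample_loh) else 0,
    }
    if summary is not None:
        report["cohort"] = {
            "n_patients": summary.n_patients,
            "n_tp53_mutant": summary.n_tp53_mutant,
            "n_tp53_variants": summary.n_tp53_variants,
            "truncating_count": summary.truncating_count,
            "truncating_pct_of_patients": summary.truncating_pct_of_patients,
            "type_counts": summary.type_counts["total"].to_dict(),
            "comparisons": {k: v.as_dict()
                            for k, v in summary.comparisons.items()},
        }
    if contingency is not None:
        report["ihc_contingency"] = {
            col: contingency[col].to_dict() for col in contingency.columns
        }
    if ihc_metrics is not None:
        report["ihc_metrics"] = ihc_metrics
    if len(other_genes):
        report["other_gene_counts"] = (
            other_genes.groupby("gene").size().to_dict())
    return report


def write_outputs(result: PipelineResult, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "variants": out / "variants.tsv",
        "loh": out / "loh.tsv",
        "loh_rates": out / "loh_rates.tsv",
        "other_genes": out / "other_genes.tsv",
        "report": out / "report.json",
    }
    tio.write_variant_table(result.classified_df, paths["variants"])
    tio.write_variant_table(result.loh_df, paths["loh"])
    tio.write_variant_table(result.loh_rates, paths["loh_rates"])
    tio.write_variant_table(result.other_genes, paths["other_genes"])
    if result.contingency is not None:
        result.contingency.to_csv(out / "ihc_contingency.tsv", sep="\t")
        paths["ihc_contingency"] = out / "ihc_contingency.tsv"
    tio.write_json_report(result.report, paths["report"])
    return paths
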