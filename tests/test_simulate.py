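"""Generator determinism, generative-model expectations, and recovery of
planted ground truth through the full pipeline."""

import hashlib
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from tp53hgsoc.pipeline import run_pipeline
from tp53hgsoc.simulate import SimParams, simulate_cohort, truth_vs_pipeline


def _hash_dir(out: Path) -> dict[str, str]:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.iterdir())}


def test_fixed_seed_gives_byte_identical_outputs(tmp_path):
    params = SimParams(n_patients=15)
    simulate_cohort(params, seed=5, out_dir=tmp_path / "a")
    simulate_cohort(params, seed=5, out_dir=tmp_path / "b")
    simulate_cohort(params, seed=6, out_dir=tmp_path / "c")
    ha, hb, hc = (_hash_dir(tmp_path / d) for d in "abc")
    assert ha == hb
    assert ha != hc


def test_generative_expectation_full_loh():
    """k=1, purity 0.6, deep coverage: mean raw VAF ≈ 0.6, normalized ≈ 1."""
    params = SimParams(n_patients=200, tp53_mutant_fraction=1.0,
                       second_variant_rate=0.0, p_k1=1.0,
                       purity_range=(0.6, 0.6), other_gene_patient_rate=0.0,
                       germline_rate=0.0, artifact_rate=0.0)
    cohort = simulate_cohort(params, seed=3)
    truth = cohort.truth
    vaf = truth["alt_reads"] / truth["total_reads"]
    assert np.allclose(truth["expected_raw_vaf"], 0.6)
    assert vaf.mean() == pytest.approx(0.6, abs=0.01)
    assert (vaf / 0.6).mean() == pytest.approx(1.0, abs=0.02)


def test_generative_expectation_no_loh_full_purity():
    """k=0 at purity 1.0 gives expected raw VAF 0.5 (heterozygous)."""
    params = SimParams(n_patients=100, tp53_mutant_fraction=1.0, p_k1=0.0,
                       purity_range=(1.0, 1.0), other_gene_patient_rate=0.0,
                       germline_rate=0.0, artifact_rate=0.0)
    cohort = simulate_cohort(params, seed=4)
    assert np.allclose(cohort.truth["expected_raw_vaf"], 0.5)


def test_estimator_consistency_with_depth():
    """k̂ concentrates on the planted k as depth grows."""
    spreads = []
    for depth in (1_000, 100_000):
        params = SimParams(n_patients=150, tp53_mutant_fraction=1.0,
                           p_k1=1.0, purity_range=(0.5, 0.5),
                           depth_median=depth, depth_sigma=1e-9,
                           depth_range=(depth, depth),
                           other_gene_patient_rate=0.0, germline_rate=0.0,
                           artifact_rate=0.0)
        truth = simulate_cohort(params, seed=8).truth
        k_hat = 2 * (truth["alt_reads"] / truth["total_reads"]) / 0.5 - 1
        spreads.append(float(np.abs(k_hat - 1.0).mean()))
    assert spreads[1] < spreads[0] / 5


def _run(cohort, out):
    return run_pipeline(
        out / "tumor.vcf", out / "normal.vcf", out / "meta.tsv",
        annotations_path=out / "annotations.tsv")


def test_planted_categories_recovered_exactly(sim_full):
    """Every planted TP53 variant that survives filtering is classified
    into its planted category (the classifier inverts the generator)."""
    cohort, out = sim_full
    result = _run(cohort, out)
    report = truth_vs_pipeline(cohort.truth, result.classified_df,
                               result.loh_df)
    cm = report.category_confusion
    for cat in ("GOF", "LOF", "unclassified"):
        off_diag = cm.loc[cat].drop(labels=[cat, "missing"], errors="ignore")
        assert int(off_diag.sum()) == 0, f"misclassified {cat}: {cm}"
    # no somatic variant lost to filtering at these depths/VAFs
    assert report.n_recovered == int(
        ((cohort.truth["gene"] == "TP53") & ~cohort.truth["is_germline"]
         & ~cohort.truth["is_artifact"]
         & (cohort.truth["alt_reads"] > 0)).sum())


def test_planted_germline_contaminants_never_survive(sim_full):
    cohort, out = sim_full
    result = _run(cohort, out)
    report = truth_vs_pipeline(cohort.truth, result.classified_df,
                               result.loh_df)
    assert report.n_germline_planted > 0
    assert report.n_germline_surviving == 0


def test_k_recovery_on_well_powered_calls(tmp_path):
    """|k̂−k| ≤ 0.1 for ≥95% of clonal TP53 variants with depth ≥ 500 and
    purity ≥ 0.3 (reported k clipped to the [0,1] parameter space).

    Uses a 400-patient simulation so the Monte-Carlo estimate of the
    recovery rate has a standard error well under 1%."""
    out = tmp_path / "sim"
    cohort = simulate_cohort(SimParams(n_patients=400), seed=101,
                             out_dir=out)
    result = _run(cohort, out)
    report = truth_vs_pipeline(cohort.truth, result.classified_df,
                               result.loh_df, k_min_depth=500,
                               k_min_purity=0.3)
    assert report.k_within_0p1 >= 0.95
    assert abs(report.k_bias) < 0.05


def test_planted_category_frequencies_within_3_sigma(sim_full):
    """Observed per-category counts lie within 3σ of the multinomial
    expectation fixed by the generator's category mix."""
    cohort, _ = sim_full
    tp53 = cohort.truth[(cohort.truth["gene"] == "TP53")
                        & ~cohort.truth["is_germline"]
                        & ~cohort.truth["is_artifact"]]
    n = len(tp53)
    observed = tp53["category"].value_counts()
    for cat, p in zip(("GOF", "LOF", "unclassified"),
                      cohort.params.category_probs):
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(observed.get(cat, 0) - n * p) <= 3 * sigma


def test_subclonal_other_gene_variants_called_subclonal(sim_full):
    cohort, out = sim_full
    result = _run(cohort, out)
    sub = cohort.truth[cohort.truth["is_subclonal"]]
    if sub.empty:
        pytest.skip("no subclonal variant planted under this seed")
    merged = sub.merge(result.loh_df,
                       on=["sample_id", "chrom", "pos", "ref", "alt"])
    assert (merged["status"] == "subclonal_variant").all()


def test_truth_vs_pipeline_rejects_unknown_keys(sim_small):
    cohort, out = sim_small
    result = _run(cohort, out)
    rogue = result.classified_df.copy()
    rogue.loc[rogue.index[0], "pos"] = 1  # key not in the truth table
    with pytest.raises(ValueError, match="not\\s+in the truth table"):
        truth_vs_pipeline(cohort.truth, rogue, result.loh_df)


def test_infeasible_parameters_rejected():
    with pytest.raises(ValueError):
        SimParams(category_probs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimParams(purity_range=(0.0, 0.5))
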