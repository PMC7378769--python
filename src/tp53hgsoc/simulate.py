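"""Synthetic-cohort generator with known ground truth.

Emulates the data-generating process of a BRCA1/2-carrier HGSOC tumor /
matched-normal panel-sequencing study under the copy-neutral LOH model:
for a planted variant with LOH cell fraction *k* in a specimen of purity
*f*, the expected raw VAF is ``f·(1+k)/2`` and the observed alt-read count
is ``Binomial(depth, expected VAF)``. The generator also plants germline
contaminants (present in tumor *and* normal at allele fraction 0.5),
low-VAF sequencing artifacts, subclonal non-TP53 oncogene variants, and
class-conditional p53 IHC staining percentages, so every pipeline stage is
testable against the recorded truth table.

Default parameters mirror the study conditions: 99 patients (78 BRCA1 /
21 BRCA2), 95/99 TP53-mutant with 2/95 carrying two variants, category
mix 22:30:45 (GOF:LOF:unclassified), pathology purity uniform on
[10%, 95%], amplicon depth lognormal with median ≈ 1087 and quartiles
≈ 735–2037, LOH mixture P(k=1)=65/94 / P(k=0)=29/94 with no intermediate
k, 6/99 patients with concomitant oncogene variants (one third subclonal
at normalized VAF 0.23–0.37), and IHC measured for 68/99 patients with
staining-class probabilities conditional on the sample's variant
category. A fixed seed fully determines the output files byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import catalog
from .catalog import VariantDef
from .types import BrcaGene, Consequence, SampleMeta, VariantCall

#: Depth lognormal sigma from the reported quartile spread:
#: ln(Q3/Q1) / (2 · 0.6745) with Q1=735, Q3=2037.
_DEPTH_SIGMA = math.log(2037 / 735) / (2 * 0.674489750196082)


@dataclass(frozen=True)
class SimParams:
    """Generator parameters; defaults are the study conditions."""

    n_patients: int = 99
    brca1_fraction: float = 78 / 99
    tp53_mutant_fraction: float = 95 / 99
    second_variant_rate: float = 2 / 95
    # Category mix among TP53 variants (GOF, LOF, unclassified).
    category_probs: tuple[float, float, float] = (22 / 97, 30 / 97, 45 / 97)
    # LOF split nonsense vs frameshift; unclassified split missense /
    # splice / inframe.
    lof_nonsense_prob: float = 15 / 30
    unclassified_missense_prob: float = 38 / 45
    unclassified_splice_prob: float = 6 / 45
    purity_range: tuple[float, float] = (0.10, 0.95)
    depth_median: float = 1087.0
    depth_sigma: float = _DEPTH_SIGMA
    depth_range: tuple[int, int] = (163, 7273)
    # Copy-neutral LOH mixture for clonal variants: P(k=1), P(k=0).
    p_k1: float = 65 / 94
    other_gene_patient_rate: float = 6 / 99
    other_gene_subclonal_prob: float = 1 / 3
    subclonal_norm_vaf_range: tuple[float, float] = (0.23, 0.37)
    germline_rate: float = 0.10
    artifact_rate: float = 0.05
    artifact_vaf_range: tuple[float, float] = (0.005, 0.04)
    ihc_fraction: float = 68 / 99
    # Staining-class probabilities (Negative, High, Intermediate, Low)
    # conditional on sample category.
    ihc_probs: dict = field(default_factory=lambda: {
        "GOF": (4 / 15, 11 / 15, 0.0, 0.0),
        "LOF": (8 / 9, 0.0, 0.0, 1 / 9),
        "unclassified": (22 / 40, 6 / 40, 9 / 40, 3 / 40),
        "wild_type": (2 / 4, 0.0, 1 / 4, 1 / 4),
    })
    # Pathology purity replicate noise ("mean difference 6 ± 4%");
    # off by default so meta carries the true purity.
    perturb_purity: bool = False
    purity_noise_sd: float = 0.06

    def __post_init__(self) -> None:
        if abs(sum(self.category_probs) - 1) > 1e-9:
            raise ValueError("category_probs must sum to 1")
        for cat, probs in self.ihc_probs.items():
            if abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"ihc_probs[{cat!r}] must sum to 1")
        lo, hi = self.purity_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("purity_range must satisfy 0 < lo <= hi <= 1")
        # Highest expected raw VAF is purity·(1+1)/2 = purity ≤ 1: feasible.


@dataclass
class SimulatedCohort:
    """In-memory result of a simulation run."""

    params: SimParams
    seed: int
    tumor_calls: list[VariantCall]
    normal_calls: list[VariantCall]
    meta: list[SampleMeta]
    truth: pd.DataFrame
    sample_ids: list[str]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write tumor.vcf, normal.vcf, meta.tsv, truth.tsv,
        annotations.tsv (deterministic for a fixed seed/params)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "tumor_vcf": out / "tumor.vcf",
            "normal_vcf": out / "normal.vcf",
            "meta": out / "meta.tsv",
            "truth": out / "truth.tsv",
            "annotations": out / "annotations.tsv",
        }
        _write_vcf(paths["tumor_vcf"], self.tumor_calls, self.sample_ids)
        _write_vcf(paths["normal_vcf"], self.normal_calls, self.sample_ids)
        meta_df = pd.DataFrame([{
            "sample_id": m.sample_id,
            "tumor_cell_pct": m.tumor_cell_pct,
            "brca_gene": m.brca_gene.value,
            "ihc_pct_positive": m.ihc_pct_positive,
        } for m in self.meta])
        meta_df.to_csv(paths["meta"], sep="\t", index=False)
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_annotation_table(paths["annotations"])
        return paths


def write_annotation_table(path: str | Path) -> None:
    """IARC-style functional annotation TSV covering the bundled catalog."""
    rows = []
    for vd in (catalog.GOF_POOL + catalog.UNCLASSIFIED_MISSENSE_POOL):
        rows.append({
            "protein_change": vd.protein_change,
            "transactivation_class": vd.transactivation_class,
            "p73_interference": "p73_interference" in vd.gof_evidence,
            "transactivation_of_repressed_genes":
                "transactivation_of_repressed_genes" in vd.gof_evidence,
            "oncogene_cooperation": "oncogene_cooperation" in vd.gof_evidence,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _draw_depth(rng: np.random.Generator, p: SimParams) -> int:
    d = rng.lognormal(math.log(p.depth_median), p.depth_sigma)
    return int(min(max(d, p.depth_range[0]), p.depth_range[1]))


def _call_from_def(vd: VariantDef, sample_id: str, alt: int, total: int) -> VariantCall:
    return VariantCall(
        sample_id=sample_id, gene=vd.gene, chrom=vd.chrom, pos=vd.pos,
        ref=vd.ref, alt=vd.alt, consequence=vd.consequence,
        protein_change=vd.protein_change, alt_reads=alt, total_reads=total,
        population_af=vd.population_af, in_cosmic=vd.in_cosmic,
        clinvar_status=vd.clinvar_status,
    )


def simulate_cohort(
    params: SimParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedCohort:
    """Generate a cohort; optionally write the files to ``out_dir``."""
    p = params or SimParams()
    rng = np.random.default_rng(seed)

    tumor_calls: list[VariantCall] = []
    normal_calls: list[VariantCall] = []
    meta: list[SampleMeta] = []
    truth_rows: list[dict] = []
    sample_ids = [f"S{i + 1:03d}" for i in range(p.n_patients)]

    for sid in sample_ids:
        brca = BrcaGene.BRCA1 if rng.random() < p.brca1_fraction else BrcaGene.BRCA2
        purity = float(rng.uniform(*p.purity_range))
        purity_pct = round(purity * 100)
        purity = purity_pct / 100.0          # meta is reported in whole percent

        planted: list[tuple[VariantDef, float, float, bool, str]] = []
        # (def, k_true [nan if subclonal], target_raw_vaf, is_tp53, label)

        tp53_cats: list[str] = []
        if rng.random() < p.tp53_mutant_fraction:
            n_var = 2 if rng.random() < p.second_variant_rate else 1
            used_sites: set = set()
            for _ in range(n_var):
                cat = ("GOF", "LOF", "unclassified")[
                    rng.choice(3, p=list(p.category_probs))]
                vd = _draw_tp53_variant(rng, p, cat, used_sites)
                if vd is None:
                    continue
                used_sites.add(vd.site)
                k = 1.0 if rng.random() < p.p_k1 else 0.0
                planted.append((vd, k, purity * (1 + k) / 2, True, cat))
                tp53_cats.append(cat)

        if rng.random() < p.other_gene_patient_rate:
            n_other = 1 + (rng.random() < 0.5)
            idx = rng.choice(len(catalog.OTHER_GENE_POOL), size=n_other,
                             replace=False)
            for j in sorted(int(i) for i in idx):
                vd = catalog.OTHER_GENE_POOL[j]
                if rng.random() < p.other_gene_subclonal_prob:
                    target_norm = float(rng.uniform(*p.subclonal_norm_vaf_range))
                    planted.append((vd, float("nan"), target_norm * purity,
                                    False, "subclonal"))
                else:
                    k = 1.0 if rng.random() < p.p_k1 else 0.0
                    planted.append((vd, k, purity * (1 + k) / 2, False, "clonal"))

        is_germline = rng.random() < p.germline_rate
        artifact_def: VariantDef | None = None
        if rng.random() < p.artifact_rate:
            pool = catalog.UNCLASSIFIED_MISSENSE_POOL
            cand = pool[int(rng.choice(len(pool)))]
            if cand.site not in {vd.site for vd, *_ in planted}:
                artifact_def = cand

        # Draw read counts.
        for vd, k, target_vaf, is_tp53, label in planted:
            depth = _draw_depth(rng, p)
            alt = int(rng.binomial(depth, target_vaf))
            tumor_calls.append(_call_from_def(vd, sid, alt, depth))
            truth_rows.append({
                "sample_id": sid, "gene": vd.gene, "chrom": vd.chrom,
                "pos": vd.pos, "ref": vd.ref, "alt": vd.alt,
                "consequence": vd.consequence.value,
                "protein_change": vd.protein_change,
                "category": label if is_tp53 else "",
                "k_true": k,
                "is_subclonal": label == "subclonal",
                "is_germline": False, "is_artifact": False,
                "purity_true": purity, "depth": depth,
                "expected_raw_vaf": target_vaf,
                "alt_reads": alt, "total_reads": depth,
            })

        if is_germline:
            vd = catalog.GERMLINE_CONTAMINANT
            depth_t, depth_n = _draw_depth(rng, p), _draw_depth(rng, p)
            alt_t = int(rng.binomial(depth_t, 0.5))
            alt_n = int(rng.binomial(depth_n, 0.5))
            tumor_calls.append(_call_from_def(vd, sid, alt_t, depth_t))
            normal_calls.append(_call_from_def(vd, sid, alt_n, depth_n))
            truth_rows.append({
                "sample_id": sid, "gene": vd.gene, "chrom": vd.chrom,
                "pos": vd.pos, "ref": vd.ref, "alt": vd.alt,
                "consequence": vd.consequence.value,
                "protein_change": vd.protein_change, "category": "",
                "k_true": float("nan"), "is_subclonal": False,
                "is_germline": True, "is_artifact": False,
                "purity_true": purity, "depth": depth_t,
                "expected_raw_vaf": 0.5,
                "alt_reads": alt_t, "total_reads": depth_t,
            })

        if artifact_def is not None:
            depth = _draw_depth(rng, p)
            vaf = float(rng.uniform(*p.artifact_vaf_range))
            alt = int(rng.binomial(depth, vaf))
            tumor_calls.append(_call_from_def(artifact_def, sid, alt, depth))
            truth_rows.append({
                "sample_id": sid, "gene": artifact_def.gene,
                "chrom": artifact_def.chrom, "pos": artifact_def.pos,
                "ref": artifact_def.ref, "alt": artifact_def.alt,
                "consequence": artifact_def.consequence.value,
                "protein_change": artifact_def.protein_change, "category": "",
                "k_true": float("nan"), "is_subclonal": False,
                "is_germline": False, "is_artifact": True,
                "purity_true": purity, "depth": depth,
                "expected_raw_vaf": vaf,
                "alt_reads": alt, "total_reads": depth,
            })

        # IHC, conditional on the sample-level category.
        ihc_pct: float | None = None
        if rng.random() < p.ihc_fraction:
            if tp53_cats:
                sample_cat = next(c for c in ("GOF", "LOF", "unclassified")
                                  if c in tp53_cats)
            else:
                sample_cat = "wild_type"
            probs = p.ihc_probs[sample_cat]
            cls = ("Negative", "High", "Intermediate", "Low")[
                rng.choice(4, p=list(probs))]
            if cls == "Negative":
                ihc_pct = 0.0
            elif cls == "High":
                ihc_pct = float(rng.integers(70, 101))
            elif cls == "Intermediate":
                ihc_pct = float(rng.integers(30, 66))
            else:
                ihc_pct = float(rng.integers(1, 11))

        reported_pct = purity_pct
        if p.perturb_purity:
            reported_pct = round(min(100, max(
                1, purity_pct + rng.normal(0, p.purity_noise_sd * 100))))
        meta.append(SampleMeta(
            sample_id=sid, tumor_cell_pct=float(reported_pct),
            brca_gene=brca, ihc_pct_positive=ihc_pct,
        ))

    truth_cols = ["sample_id", "gene", "chrom", "pos", "ref", "alt",
                  "consequence", "protein_change", "category", "k_true",
                  "is_subclonal", "is_germline", "is_artifact", "purity_true",
                  "depth", "expected_raw_vaf", "alt_reads", "total_reads"]
    truth = pd.DataFrame(truth_rows, columns=truth_cols)
    cohort = SimulatedCohort(
        params=p, seed=seed, tumor_calls=tumor_calls,
        normal_calls=normal_calls, meta=meta, truth=truth,
        sample_ids=sample_ids,
    )
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort


def _draw_tp53_variant(
    rng: np.random.Generator, p: SimParams, category: str, used: set,
) -> VariantDef | None:
    if category == "GOF":
        pool = catalog.GOF_POOL
    elif category == "LOF":
        pool = (catalog.NONSENSE_POOL if rng.random() < p.lof_nonsense_prob
                else catalog.FRAMESHIFT_POOL)
    else:
        u = rng.random()
        if u < p.unclassified_missense_prob:
            pool = catalog.UNCLASSIFIED_MISSENSE_POOL
        elif u < p.unclassified_missense_prob + p.unclassified_splice_prob:
            pool = catalog.SPLICE_POOL
        else:
            pool = catalog.INFRAME_POOL
    candidates = [vd for vd in pool if vd.site not in used]
    if not candidates:
        return None
    return candidates[int(rng.choice(len(candidates)))]


# -- VCF writing ------------------------------------------------------------

def _build_header(sample_ids: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in catalog.CONTIGS:
        header.add_line(f"##contig=<ID={name},length={length}>")
    header.add_line('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">')
    header.add_line('##INFO=<ID=CONS,Number=1,Type=String,Description="Coding consequence">')
    header.add_line('##INFO=<ID=PAA,Number=1,Type=String,Description="Protein change (HGVS short form)">')
    header.add_line('##INFO=<ID=POPAF,Number=1,Type=Float,Description="Population allele frequency">')
    header.add_line('##INFO=<ID=COSMIC,Number=0,Type=Flag,Description="Catalogued somatic variant">')
    header.add_line('##INFO=<ID=CLNSIG,Number=1,Type=String,Description="ClinVar significance">')
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths (ref, alt)">')
    for sid in sample_ids:
        header.add_sample(sid)
    return header


def _write_vcf(path: Path, calls: list[VariantCall], sample_ids: list[str]) -> None:
    """Multi-sample single-ALT-per-record VCF; samples without the allele
    get a reference-only AD of (1087, 0)."""
    contig_order = {name: i for i, (name, _) in enumerate(catalog.CONTIGS)}
    by_site: dict[tuple, dict[str, VariantCall]] = {}
    site_def: dict[tuple, VariantCall] = {}
    for c in calls:
        by_site.setdefault(c.site, {})[c.sample_id] = c
        site_def.setdefault(c.site, c)
    header = _build_header(sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sorted(by_site, key=lambda s: (contig_order[s[0]], s[1], s[2], s[3])):
            chrom, pos, ref, alt = site
            proto = site_def[site]
            rec = vcf.new_record(contig=chrom, start=pos - 1,
                                 alleles=(ref, alt))
            rec.info["GENE"] = proto.gene
            rec.info["CONS"] = proto.consequence.value
            if proto.protein_change:
                rec.info["PAA"] = proto.protein_change
            if proto.population_af is not None:
                rec.info["POPAF"] = proto.population_af
            if proto.in_cosmic:
                rec.info["COSMIC"] = True
            if proto.clinvar_status.value != "absent":
                rec.info["CLNSIG"] = proto.clinvar_status.value
            for sid in sample_ids:
                call = by_site[site].get(sid)
                if call is None:
                    rec.samples[sid]["AD"] = (1087, 0)
                else:
                    rec.samples[sid]["AD"] = (
                        call.total_reads - call.alt_reads, call.alt_reads)
            vcf.write(rec)


# -- truth vs pipeline ------------------------------------------------------

@dataclass
class RecoveryReport:
    """Comparison of pipeline output against the generator's truth."""

    category_confusion: pd.DataFrame   # truth category × pipeline category
    status_confusion: pd.DataFrame     # truth status × pipeline status
    k_bias: float
    k_rmse: float
    k_within_0p1: float                # fraction of clonal TP53 calls with |k̂−k|≤0.1
    n_germline_planted: int
    n_germline_surviving: int
    n_truth_variants: int
    n_recovered: int

    def as_dict(self) -> dict:
        return {
            "k_bias": self.k_bias, "k_rmse": self.k_rmse,
            "k_within_0p1": self.k_within_0p1,
            "n_germline_planted": self.n_germline_planted,
            "n_germline_surviving": self.n_germline_surviving,
            "n_truth_variants": self.n_truth_variants,
            "n_recovered": self.n_recovered,
        }


_KEY = ["sample_id", "chrom", "pos", "ref", "alt"]


def truth_vs_pipeline(
    truth: pd.DataFrame,
    classified: pd.DataFrame,
    loh: pd.DataFrame,
    *,
    k_min_depth: int = 0,
    k_min_purity: float = 0.0,
) -> RecoveryReport:
    """Confusion matrices and k-recovery statistics.

    ``classified`` and ``loh`` are the pipeline's per-variant frames
    (from :func:`~tp53hgsoc.classify.classified_to_frame` and
    :func:`~tp53hgsoc.loh.loh_to_frame`). Pipeline rows whose keys are
    absent from the truth table are a hard error.

    The k-recovery statistics use the reported estimate, clipped to the
    parameter space [0, 1] (k is a cell fraction), and can be restricted
    to well-powered calls via ``k_min_depth`` / ``k_min_purity``.
    """
    truth = truth.copy()
    truth["sample_id"] = truth["sample_id"].astype(str)
    truth_keys = set(map(tuple, truth[_KEY].itertuples(index=False)))
    for frame, name in ((classified, "classified"), (loh, "loh")):
        if frame.empty:
            continue
        keys = set(map(tuple, frame[_KEY].astype(truth[_KEY].dtypes.to_dict())
                       [_KEY].itertuples(index=False)))
        extra = keys - truth_keys
        if extra:
            raise ValueError(f"{name} output contains {len(extra)} keys not "
                             f"in the truth table, e.g. {sorted(extra)[:3]}")

    # Category recovery over genuine TP53 variants.
    tp53_truth = truth[(truth["gene"] == "TP53") & ~truth["is_germline"]
                       & ~truth["is_artifact"]].copy()
    merged = tp53_truth.merge(
        classified[_KEY + ["category"]].rename(columns={"category": "called"}),
        on=_KEY, how="left")
    merged["called"] = merged["called"].fillna("missing")
    category_confusion = pd.crosstab(merged["category"], merged["called"])

    # Status recovery: truth status implied by the planted k / subclonality.
    def _truth_status(row) -> str:
        if row["is_subclonal"]:
            return "subclonal_variant"
        if row["k_true"] == 1.0:
            return "LOH_positive_clonal"
        if row["k_true"] == 0.0:
            return "no_LOH_clonal"
        return "none"

    somatic = truth[~truth["is_germline"] & ~truth["is_artifact"]].copy()
    somatic["truth_status"] = somatic.apply(_truth_status, axis=1)
    smerged = somatic.merge(
        loh[_KEY + ["status", "k_hat"]], on=_KEY, how="left")
    smerged["status"] = smerged["status"].fillna("missing")
    status_confusion = pd.crosstab(smerged["truth_status"], smerged["status"])

    clonal = smerged[(smerged["gene"] == "TP53")
                     & smerged["k_true"].isin([0.0, 1.0])
                     & smerged["k_hat"].notna()
                     & (smerged["depth"] >= k_min_depth)
                     & (smerged["purity_true"] >= k_min_purity)]
    if len(clonal):
        err = clonal["k_hat"].clip(0.0, 1.0) - clonal["k_true"]
        k_bias = float(err.mean())
        k_rmse = float(np.sqrt((err ** 2).mean()))
        k_within = float((err.abs() <= 0.1).mean())
    else:
        k_bias = k_rmse = k_within = float("nan")

    germ = truth[truth["is_germline"]]
    germ_keys = set(map(tuple, germ[_KEY].itertuples(index=False)))
    if classified.empty:
        surv = 0
    else:
        called_keys = set(map(tuple, classified[_KEY].itertuples(index=False)))
        surv = len(germ_keys & called_keys)

    return RecoveryReport(
        category_confusion=category_confusion,
        status_confusion=status_confusion,
        k_bias=k_bias, k_rmse=k_rmse, k_within_0p1=k_within,
        n_germline_planted=len(germ),
        n_germline_surviving=surv,
        n_truth_variants=len(somatic),
        n_recovered=int(merged["called"].ne("missing").sum()),
    )
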