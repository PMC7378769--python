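"""Reading and writing the pipeline's external formats.

Two variant input dialects are supported:

* **VCF 4.x** (tumor and matched-normal files), read with :mod:`pysam`.
  Allele depths are taken from the per-sample ``AD`` FORMAT field; the
  annotations the pipeline needs travel in INFO keys ``GENE``, ``CONS``
  (consequence), ``PAA`` (protein change, any HGVS spelling), ``POPAF``
  (population allele frequency), ``COSMIC`` (flag) and ``CLNSIG``.
  Multi-allelic records are split into one call per ALT allele and
  multi-sample files into one call per carrying sample (alt depth > 0).

* **TSV** with fixed column names (``sample_id``, ``gene``, ``chrom``,
  ``pos``, ``ref``, ``alt``, ``consequence``, ``protein_change``,
  ``alt_reads``, ``total_reads`` and optional ``population_af``,
  ``in_cosmic``, ``clinvar_status``), the shape of a supplementary table.

Annotation resources (GOF hotspot list, IARC-style functional annotations,
reference category counts) are plain TSV tables.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import pysam

from .hgvs import normalize_protein_change
from .types import (
    BrcaGene,
    ClinvarStatus,
    ReferenceCohort,
    SampleMeta,
    VariantCall,
    parse_consequence,
)

logger = logging.getLogger(__name__)

TSV_COLUMNS = [
    "sample_id", "gene", "chrom", "pos", "ref", "alt",
    "consequence", "protein_change", "alt_reads", "total_reads",
]
OPTIONAL_TSV_COLUMNS = ["population_af", "in_cosmic", "clinvar_status"]


def _parse_clinvar(value) -> ClinvarStatus:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ClinvarStatus.ABSENT
    v = str(value).strip().lower().replace(" ", "_")
    if v in {"", ".", "na", "nan", "absent"}:
        return ClinvarStatus.ABSENT
    if v == "pathogenic":
        return ClinvarStatus.PATHOGENIC
    if v in {"likely_pathogenic", "pathogenic/likely_pathogenic"}:
        return ClinvarStatus.LIKELY_PATHOGENIC
    return ClinvarStatus.OTHER


def _info_flag(info, key) -> bool:
    try:
        return bool(info.get(key, False))
    except ValueError:           # key not declared in this file's header
        return False


def _info_scalar(info, key, index: int, default=None):
    """INFO fields may be per-ALT tuples (Number=A) or scalars."""
    if key not in info:
        return default
    v = info[key]
    if isinstance(v, tuple):
        return v[index] if index < len(v) else default
    return v


def read_variant_calls(path: str | Path, source: str = "tumor") -> list[VariantCall]:
    """Read somatic calls from a VCF 4.x or TSV file.

    ``source`` is a label ("tumor" or "normal") used only in error
    messages; both files share a format. Returns one :class:`VariantCall`
    per (sample, ALT allele) with nonzero alt depth.
    """
    path = Path(path)
    if path.suffix.lower() in {".tsv", ".txt", ".csv"}:
        return _read_variant_tsv(path)
    return _read_variant_vcf(path, source)


def _read_variant_vcf(path: Path, source: str) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts):
                cons_str = _info_scalar(rec.info, "CONS", alt_idx, "other") or "other"
                consequence, recognized = parse_consequence(str(cons_str))
                if not recognized:
                    logger.warning(
                        "unknown consequence %r at %s:%s mapped to 'other'",
                        cons_str, rec.chrom, rec.pos,
                    )
                gene = str(_info_scalar(rec.info, "GENE", alt_idx, "") or "")
                paa = str(_info_scalar(rec.info, "PAA", alt_idx, "") or "")
                popaf = _info_scalar(rec.info, "POPAF", alt_idx)
                clnsig = _info_scalar(rec.info, "CLNSIG", alt_idx)
                in_cosmic = _info_flag(rec.info, "COSMIC")
                for sample in samples:
                    fmt = rec.samples[sample]
                    ad = fmt.get("AD")
                    if ad is None or all(x is None for x in ad):
                        raise ValueError(
                            f"{source} VCF record {rec.chrom}:{rec.pos} "
                            f"{rec.ref}>{alt} sample {sample}: no AD allele depths"
                        )
                    ref_reads = int(ad[0] or 0)
                    alt_reads = int(ad[alt_idx + 1] or 0)
                    if alt_reads == 0:
                        continue  # sample does not carry this allele
                    total = ref_reads + sum(int(x or 0) for x in ad[1:])
                    calls.append(VariantCall(
                        sample_id=sample,
                        gene=gene,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        consequence=consequence,
                        protein_change=normalize_protein_change(paa),
                        alt_reads=alt_reads,
                        total_reads=total,
                        population_af=float(popaf) if popaf is not None else None,
                        in_cosmic=in_cosmic,
                        clinvar_status=_parse_clinvar(clnsig),
                    ))
    return calls


def _read_variant_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    calls = []
    for row in df.itertuples(index=False):
        if pd.isna(row.alt_reads) or pd.isna(row.total_reads):
            raise ValueError(
                f"{path}: missing read depths for {row.sample_id} "
                f"{row.chrom}:{row.pos} {row.ref}>{row.alt}"
            )
        consequence, recognized = parse_consequence(str(row.consequence))
        if not recognized:
            logger.warning("unknown consequence %r mapped to 'other'", row.consequence)
        popaf = getattr(row, "population_af", None)
        if popaf is not None and pd.isna(popaf):
            popaf = None
        in_cosmic = bool(getattr(row, "in_cosmic", False))
        calls.append(VariantCall(
            sample_id=str(row.sample_id),
            gene=str(row.gene),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            consequence=consequence,
            protein_change=normalize_protein_change(
                "" if pd.isna(row.protein_change) else str(row.protein_change)),
            alt_reads=int(row.alt_reads),
            total_reads=int(row.total_reads),
            population_af=float(popaf) if popaf is not None else None,
            in_cosmic=in_cosmic,
            clinvar_status=_parse_clinvar(getattr(row, "clinvar_status", None)),
        ))
    return calls


def vcf_sample_ids(path: str | Path) -> list[str]:
    """Sample columns declared in a VCF header (present even for samples
    with no surviving variant records)."""
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.samples)


def read_sample_meta(path: str | Path) -> tuple[list[SampleMeta], pd.DataFrame]:
    """Read the per-sample metadata TSV.

    Required columns: ``sample_id``, ``tumor_cell_pct``; optional
    ``brca_gene`` and ``ihc_pct_positive``. Rows violating the invariants
    (e.g. tumor_cell_pct outside (0,100]) are rejected, not fatal.

    Returns (accepted rows, rejection report DataFrame).
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "tumor_cell_pct"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    accepted: list[SampleMeta] = []
    rejects: list[dict] = []
    for row in df.itertuples(index=False):
        try:
            brca = BrcaGene(str(getattr(row, "brca_gene", "none")))
        except ValueError:
            brca = BrcaGene.NONE
        ihc = getattr(row, "ihc_pct_positive", None)
        if ihc is not None and pd.isna(ihc):
            ihc = None
        try:
            accepted.append(SampleMeta(
                sample_id=str(row.sample_id),
                tumor_cell_pct=float(row.tumor_cell_pct),
                brca_gene=brca,
                ihc_pct_positive=float(ihc) if ihc is not None else None,
            ))
        except (ValueError, TypeError) as exc:
            rejects.append({"sample_id": row.sample_id, "reason": str(exc)})
    report = pd.DataFrame(rejects, columns=["sample_id", "reason"])
    if len(report):
        logger.warning("rejected %d metadata rows", len(report))
    return accepted, report


# -- annotation resources ---------------------------------------------------

def read_gof_list(path: str | Path | None = None) -> frozenset[str]:
    """Load the GOF hotspot list (TSV with a ``protein_change`` column).

    Without a path, the bundled default list is used: the eight oncomorphic
    hotspot mutations expanded to eleven explicit protein changes
    (R248Q/W and R273C/H/L counted separately).
    """
    if path is None:
        from importlib.resources import files
        path = files("tp53hgsoc").joinpath("data/gof_hotspots.tsv")
        df = pd.read_csv(str(path), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return frozenset(normalize_protein_change(p) for p in df["protein_change"])


def read_iarc_annotations(path: str | Path) -> pd.DataFrame:
    """Functional-annotation table: ``protein_change``,
    ``transactivation_class`` and three boolean GOF-evidence columns
    (``p73_interference``, ``transactivation_of_repressed_genes``,
    ``oncogene_cooperation``)."""
    df = pd.read_csv(path, sep="\t")
    df["protein_change"] = df["protein_change"].map(normalize_protein_change)
    for col in ("p73_interference", "transactivation_of_repressed_genes",
                "oncogene_cooperation"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
        else:
            df[col] = False
    if "transactivation_class" not in df.columns:
        df["transactivation_class"] = "unknown"
    return df.set_index("protein_change", drop=False)


def read_reference_counts(path: str | Path) -> ReferenceCohort:
    """Reference-count TSV with columns ``category``, ``count``,
    ``n_cases`` (n_cases repeated on every row)."""
    df = pd.read_csv(path, sep="\t")
    n_cases = int(df["n_cases"].iloc[0])
    counts = {str(r.category): int(r.count) for r in df.itertuples(index=False)}
    return ReferenceCohort(n_cases=n_cases, counts=counts)


# -- reports ----------------------------------------------------------------

def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_variant_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json_report(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    import numpy as np
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "value"):  # enums
        return obj.value
    raise TypeError(f"not JSON serializable: {type(obj)}")
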