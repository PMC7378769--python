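"""Loss-of-heterozygosity inference from purity-normalized allele frequency.

Model
-----
In a specimen with tumor-cell fraction *f* (pathology purity), a clonal
heterozygous somatic variant contributes half the alleles of each tumor
cell. Under copy-neutral LOH, a fraction *k* of tumor cells has lost the
wild-type allele and carries two mutant copies, so the expected raw VAF is

    VAF = f · (1 + k) / 2

Dividing by *f* gives the purity-normalized VAF,

    normalized VAF = VAF / f = (1 + k) / 2,

which inverts to ``k = 2·normVAF − 1``: normalized VAF 0.5 means no LOH
(k = 0) and 1.0 means LOH in all tumor cells (k = 100%).

Clonality calls are banded: normalized VAF within 0.50 ± 0.05 is called
clonal without LOH, within 1.00 ± 0.08 clonal with LOH (the empirical
spreads observed around the two theoretical points, promoted here to an
explicit decision rule), below 0.45 subclonal (the variant is confined to
a subclone, so k is not interpretable), and anything else anomalous —
covering both the unobserved gap (0.55, 0.92), where 0 < k < 1 would be
implied, and artifacts with normalized VAF above the LOH band (e.g.
amplification-ratio deviations producing values like 1.6).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import ClassifiedVariant
from .types import SampleMeta, VariantCall

#: Clonality statuses.
NO_LOH_CLONAL = "no_LOH_clonal"
LOH_POSITIVE_CLONAL = "LOH_positive_clonal"
SUBCLONAL = "subclonal_variant"
ANOMALOUS = "anomalous"

CLONAL_STATUSES = (NO_LOH_CLONAL, LOH_POSITIVE_CLONAL)


@dataclass(frozen=True)
class BandParams:
    """Decision bands on normalized VAF (inclusive edges)."""

    no_loh_center: float = 0.50
    no_loh_halfwidth: float = 0.05
    loh_center: float = 1.00
    loh_halfwidth: float = 0.08
    subclonal_below: float = 0.45

    def __post_init__(self) -> None:
        no_hi = self.no_loh_center + self.no_loh_halfwidth
        loh_lo = self.loh_center - self.loh_halfwidth
        if no_hi >= loh_lo:
            raise ValueError("no-LOH and LOH bands overlap")
        if self.subclonal_below > self.no_loh_center - self.no_loh_halfwidth:
            raise ValueError("subclonal threshold intrudes into the no-LOH band")


@dataclass(frozen=True)
class LOHCall:
    """Per-variant LOH/clonality call."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    raw_vaf: float
    tumor_cell_fraction: float
    norm_vaf: float
    k_hat: float                   # 2·norm_vaf − 1, unclipped
    status: str

    @property
    def k_hat_clipped(self) -> float:
        """k clipped to [-1, 2] for reporting; the raw value is k_hat."""
        return min(2.0, max(-1.0, self.k_hat))


def normalize_vaf(raw_vaf: float, tumor_cell_fraction: float) -> float:
    """Purity-normalized VAF: raw VAF divided by the tumor-cell fraction.

    May exceed 1 for artifacts (unequal allele amplification).
    """
    if not 0 < tumor_cell_fraction <= 1:
        raise ValueError(
            f"tumor_cell_fraction must be in (0,1], got {tumor_cell_fraction}"
        )
    if not 0 <= raw_vaf <= 1:
        raise ValueError(f"raw_vaf outside [0,1]: {raw_vaf}")
    return raw_vaf / tumor_cell_fraction


def estimate_k(norm_vaf: float) -> float:
    """Fraction of tumor cells with LOH implied by a normalized VAF.

    Inverts normVAF = (1+k)/2. Values outside [0,1] indicate that the
    clonal copy-neutral model does not apply (subclonal variant or
    artifact); they are returned unclipped.
    """
    if norm_vaf < 0:
        raise ValueError(f"norm_vaf must be non-negative, got {norm_vaf}")
    return 2.0 * norm_vaf - 1.0


def call_status(norm_vaf: float, bands: BandParams | None = None) -> str:
    """Banded clonality/LOH status for one normalized VAF (see module doc)."""
    bands = bands or BandParams()
    if (bands.no_loh_center - bands.no_loh_halfwidth
            <= norm_vaf <= bands.no_loh_center + bands.no_loh_halfwidth):
        return NO_LOH_CLONAL
    if (bands.loh_center - bands.loh_halfwidth
            <= norm_vaf <= bands.loh_center + bands.loh_halfwidth):
        return LOH_POSITIVE_CLONAL
    if norm_vaf < bands.subclonal_below:
        return SUBCLONAL
    return ANOMALOUS


def infer_loh(
    calls: list[VariantCall],
    meta: list[SampleMeta] | dict[str, SampleMeta],
    bands: BandParams | None = None,
) -> list[LOHCall]:
    """Compute an independent LOHCall for every variant call.

    A sample carrying two variants gets one call per variant;
    sample-level LOH status is positive if any call is clonal-LOH.
    """
    bands = bands or BandParams()
    if not isinstance(meta, dict):
        meta = {m.sample_id: m for m in meta}
    out = []
    for call in calls:
        if call.sample_id not in meta:
            raise KeyError(f"no metadata for sample {call.sample_id!r}")
        f = meta[call.sample_id].tumor_cell_fraction
        nv = normalize_vaf(call.vaf, f)
        out.append(LOHCall(
            sample_id=call.sample_id, chrom=call.chrom, pos=call.pos,
            ref=call.ref, alt=call.alt,
            raw_vaf=call.vaf, tumor_cell_fraction=f,
            norm_vaf=nv, k_hat=estimate_k(nv), status=call_status(nv, bands),
        ))
    return out


def loh_to_frame(loh_calls: list[LOHCall]) -> pd.DataFrame:
    rows = [{
        "sample_id": c.sample_id, "chrom": c.chrom, "pos": c.pos,
        "ref": c.ref, "alt": c.alt, "raw_vaf": c.raw_vaf,
        "tumor_cell_fraction": c.tumor_cell_fraction,
        "norm_vaf": c.norm_vaf, "k_hat": c.k_hat,
        "k_hat_clipped": c.k_hat_clipped, "status": c.status,
    } for c in loh_calls]
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "raw_vaf",
            "tumor_cell_fraction", "norm_vaf", "k_hat", "k_hat_clipped",
            "status"]
    return pd.DataFrame(rows, columns=cols)


def sample_loh_status(loh_calls: list[LOHCall]) -> pd.DataFrame:
    """Sample-level LOH: positive if any variant call in the sample is
    clonal-LOH."""
    df = loh_to_frame(loh_calls)
    if df.empty:
        return pd.DataFrame(columns=["sample_id", "loh_positive"])
    agg = (df.assign(is_loh=df["status"] == LOH_POSITIVE_CLONAL)
             .groupby("sample_id", as_index=False)["is_loh"].any()
             .rename(columns={"is_loh": "loh_positive"}))
    return agg


def loh_rate_by_category(
    loh_calls: list[LOHCall],
    classified: list[ClassifiedVariant],
) -> pd.DataFrame:
    """Counts and LOH-positive rates per functional category and per
    consequence.

    The LOH-positive rate is taken over *clonal* calls only
    (LOH-positive / (LOH-positive + no-LOH)); subclonal and anomalous
    calls are counted separately.
    """
    loh_df = loh_to_frame(loh_calls)
    cls_rows = [{
        "sample_id": cv.call.sample_id, "chrom": cv.call.chrom,
        "pos": cv.call.pos, "ref": cv.call.ref, "alt": cv.call.alt,
        "category": cv.category.value,
        "consequence": cv.call.consequence.value,
    } for cv in classified]
    cols = ["group_by", "group", "n", "n_loh_positive", "n_no_loh",
            "n_subclonal", "n_anomalous", "loh_rate"]
    if loh_df.empty or not cls_rows:
        return pd.DataFrame(columns=cols)
    merged = loh_df.merge(pd.DataFrame(cls_rows),
                          on=["sample_id", "chrom", "pos", "ref", "alt"],
                          how="inner")
    out_rows = []
    for group_by in ("category", "consequence"):
        for group, sub in merged.groupby(group_by, sort=True):
            n_loh = int((sub["status"] == LOH_POSITIVE_CLONAL).sum())
            n_no = int((sub["status"] == NO_LOH_CLONAL).sum())
            n_sub = int((sub["status"] == SUBCLONAL).sum())
            n_anom = int((sub["status"] == ANOMALOUS).sum())
            clonal = n_loh + n_no
            out_rows.append({
                "group_by": group_by, "group": group, "n": len(sub),
                "n_loh_positive": n_loh, "n_no_loh": n_no,
                "n_subclonal": n_sub, "n_anomalous": n_anom,
                "loh_rate": n_loh / clonal if clonal else float("nan"),
            })
    return pd.DataFrame(out_rows, columns=cols)
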