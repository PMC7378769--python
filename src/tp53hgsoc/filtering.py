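"""Variant-retention rules turning raw somatic calls into the analyzable set.

A tumor call is kept iff all of the following hold:

1. at least ``min_alt_reads`` (default 6) reads support the alternative
   allele;
2. tumor VAF ≥ ``min_tumor_vaf`` (default 5%);
3. the same (chrom, pos, ref, alt) is not present in the matched normal
   sample at VAF ≥ ``normal_vaf_germline`` (default 20%) — such calls are
   germline, not somatic;
4. the variant type is admitted: truncating/splice-disrupting consequences
   unconditionally; missense and splice-region variants only if rare in the
   population (< ``max_population_af``, default 0.5%) or catalogued; any
   variant (including synonymous) if flagged in COSMIC or annotated
   pathogenic / likely pathogenic in ClinVar.

Every rejected call carries exactly one primary reason code, checked in the
order min_alt_reads → min_vaf → germline → variant_type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import ClinvarStatus, Consequence, VariantCall

#: Consequences admitted unconditionally (rule 1 of the type rules).
DISRUPTIVE_CONSEQUENCES = frozenset({
    Consequence.FRAMESHIFT,
    Consequence.NONSENSE,
    Consequence.STOP_LOST,
    Consequence.START_LOST,
    Consequence.SPLICE_ACCEPTOR,
    Consequence.SPLICE_DONOR,
})

#: Consequences admitted when rare in the population (rule 2).
RARE_ADMITTED_CONSEQUENCES = frozenset({
    Consequence.MISSENSE,
    Consequence.SPLICE_REGION,
})


@dataclass(frozen=True)
class FilterParams:
    min_alt_reads: int = 6
    min_tumor_vaf: float = 0.05
    normal_vaf_germline: float = 0.20
    max_population_af: float = 0.005


@dataclass
class RejectedCall:
    call: VariantCall
    reason: str                    # primary reason code


@dataclass
class FilterResult:
    kept: list[VariantCall] = field(default_factory=list)
    rejected: list[RejectedCall] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.rejected)


def admit_by_type(call: VariantCall, params: FilterParams | None = None) -> tuple[bool, str]:
    """Pure predicate for the four variant-type admission rules.

    Returns (admitted, reason): reason names the first rule that admits
    the call, or ``"variant_type"`` when none does.
    """
    params = params or FilterParams()
    if call.consequence in DISRUPTIVE_CONSEQUENCES:
        return True, "disruptive_consequence"
    if call.consequence in RARE_ADMITTED_CONSEQUENCES:
        # Missing population AF is treated as rare: genuinely rare somatic
        # variants typically have no population-catalogue record.
        if call.population_af is None or call.population_af < params.max_population_af:
            return True, "rare_missense_or_splice_region"
    if call.in_cosmic:
        return True, "cosmic"
    if call.clinvar_status in (ClinvarStatus.PATHOGENIC,
                               ClinvarStatus.LIKELY_PATHOGENIC):
        return True, "clinvar_pathogenic"
    return False, "variant_type"


def filter_somatic(
    tumor_calls: list[VariantCall],
    normal_calls: list[VariantCall],
    params: FilterParams | None = None,
    *,
    normal_samples: set[str] | None = None,
    allow_missing_normal: bool = False,
) -> FilterResult:
    """Apply the retention rules to tumor calls against matched normals.

    ``normal_samples`` is the full set of samples for which a matched
    normal was sequenced (a sample with zero normal variant calls is still
    matched); when omitted it is inferred from ``normal_calls``. A tumor
    call from a sample with no matched normal raises unless
    ``allow_missing_normal`` is set.
    """
    params = params or FilterParams()
    if normal_samples is None:
        normal_samples = {c.sample_id for c in normal_calls}

    germline_sites: set[tuple] = {
        c.key for c in normal_calls if c.vaf >= params.normal_vaf_germline
    }

    result = FilterResult()
    for call in tumor_calls:
        if not allow_missing_normal and call.sample_id not in normal_samples:
            raise ValueError(
                f"sample {call.sample_id!r} has no matched normal; "
                "pass allow_missing_normal=True to filter without one"
            )
        if call.alt_reads < params.min_alt_reads:
            result.rejected.append(RejectedCall(call, "min_alt_reads"))
            continue
        if call.vaf < params.min_tumor_vaf:
            result.rejected.append(RejectedCall(call, "min_vaf"))
            continue
        if call.key in germline_sites:
            result.rejected.append(RejectedCall(call, "germline"))
            continue
        admitted, type_reason = admit_by_type(call, params)
        if not admitted:
            result.rejected.append(RejectedCall(call, type_reason))
            continue
        result.kept.append(call)
    return result
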