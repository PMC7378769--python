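"""Shared data model for the pipeline.

All records are plain frozen dataclasses; coordinates follow the 1-based VCF
convention throughout.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

from .hgvs import normalize_protein_change


class Consequence(str, enum.Enum):
    """Coding consequence of a variant, collapsed to the classes the
    retention and classification rules distinguish."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"          # stop_gained
    FRAMESHIFT = "frameshift"
    STOP_LOST = "stop_lost"
    START_LOST = "start_lost"
    SPLICE_ACCEPTOR = "splice_acceptor"
    SPLICE_DONOR = "splice_donor"
    SPLICE_REGION = "splice_region"
    INFRAME_DELETION = "inframe_deletion"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


# Sequence-ontology / VEP style terms mapped onto the internal enum.
CONSEQUENCE_ALIASES: dict[str, Consequence] = {
    "missense_variant": Consequence.MISSENSE,
    "stop_gained": Consequence.NONSENSE,
    "nonsense_variant": Consequence.NONSENSE,
    "frameshift_variant": Consequence.FRAMESHIFT,
    "frameshift_deletion": Consequence.FRAMESHIFT,
    "frameshift_insertion": Consequence.FRAMESHIFT,
    "stop_lost": Consequence.STOP_LOST,
    "start_lost": Consequence.START_LOST,
    "splice_acceptor_variant": Consequence.SPLICE_ACCEPTOR,
    "splice_donor_variant": Consequence.SPLICE_DONOR,
    "splice_region_variant": Consequence.SPLICE_REGION,
    "inframe_deletion": Consequence.INFRAME_DELETION,
    "disruptive_inframe_deletion": Consequence.INFRAME_DELETION,
    "synonymous_variant": Consequence.SYNONYMOUS,
}


def parse_consequence(value: str) -> tuple["Consequence", bool]:
    """Map a consequence string to the internal enum.

    Returns (consequence, recognized). Unknown strings map to OTHER with
    recognized=False so callers can log a warning.
    """
    v = value.strip().lower()
    try:
        return Consequence(v), True
    except ValueError:
        pass
    if v in CONSEQUENCE_ALIASES:
        return CONSEQUENCE_ALIASES[v], True
    return Consequence.OTHER, False


class ClinvarStatus(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    OTHER = "other"
    ABSENT = "absent"


class Category(str, enum.Enum):
    """Functional category of a TP53 variant."""

    GOF = "GOF"
    LOF = "LOF"
    UNCLASSIFIED = "unclassified"


VariantKey = tuple[str, str, int, str, str]  # (sample_id, chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One somatic call with read support and annotations."""

    sample_id: str
    gene: str
    chrom: str
    pos: int                       # 1-based, VCF convention
    ref: str
    alt: str
    consequence: Consequence
    protein_change: str            # normalized one-letter HGVS short form
    alt_reads: int
    total_reads: int
    population_af: float | None = None
    in_cosmic: bool = False
    clinvar_status: ClinvarStatus = ClinvarStatus.ABSENT

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"total_reads must be positive, got {self.total_reads}")
        if not 0 <= self.alt_reads <= self.total_reads:
            raise ValueError(
                f"alt_reads {self.alt_reads} outside [0, total_reads={self.total_reads}]"
            )
        if self.population_af is not None and not 0 <= self.population_af <= 1:
            raise ValueError(f"population_af outside [0,1]: {self.population_af}")
        norm = normalize_protein_change(self.protein_change)
        if norm != self.protein_change:
            object.__setattr__(self, "protein_change", norm)

    @property
    def vaf(self) -> float:
        """Variant allele frequency: alt-supporting reads / total reads."""
        return self.alt_reads / self.total_reads

    @property
    def key(self) -> VariantKey:
        return (self.sample_id, self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int, str, str]:
        """(chrom, pos, ref, alt) — the sample-independent part of the key."""
        return (self.chrom, self.pos, self.ref, self.alt)


class BrcaGene(str, enum.Enum):
    BRCA1 = "BRCA1"
    BRCA2 = "BRCA2"
    NONE = "none"


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample pathology metadata."""

    sample_id: str
    tumor_cell_pct: float          # pathology purity estimate, in (0, 100]
    brca_gene: BrcaGene = BrcaGene.NONE
    ihc_pct_positive: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.tumor_cell_pct <= 100:
            raise ValueError(
                f"tumor_cell_pct must be in (0,100], got {self.tumor_cell_pct}"
            )
        if self.ihc_pct_positive is not None and not 0 <= self.ihc_pct_positive <= 100:
            raise ValueError(
                f"ihc_pct_positive outside [0,100]: {self.ihc_pct_positive}"
            )

    @property
    def tumor_cell_fraction(self) -> float:
        return self.tumor_cell_pct / 100.0


@dataclass(frozen=True)
class ReferenceCohort:
    """Category counts for a reference variant set (e.g. an IARC-style
    HGSOC collection) used in the frequency comparison."""

    n_cases: int
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        for cat, n in self.counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cat}")
        if sum(self.counts.values()) > self.n_cases * len(self.counts):
            raise ValueError("category counts inconsistent with n_cases")

    def proportion(self, category: str) -> float:
        return self.counts[category] / self.n_cases


__all__ = [
    "BrcaGene",
    "Category",
    "ClinvarStatus",
    "Consequence",
    "CONSEQUENCE_ALIASES",
    "parse_consequence",
    "ReferenceCohort",
    "SampleMeta",
    "VariantCall",
    "VariantKey",
    "replace",
]
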