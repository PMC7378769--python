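"""Bundled variant catalog for the synthetic-cohort generator.

Each entry fixes a plausible genomic identity (chrom/pos/ref/alt on a
deterministic synthetic coordinate layout — positions are stable
identifiers, not real genome coordinates), a consequence, a protein
change, and catalogue/annotation attributes. The TP53 pools cover the
eleven GOF hotspot changes, recurrent truncating variants, non-hotspot
DNA-binding-domain / tetramerization-domain / spacer missense changes,
splice variants and an inframe deletion; the other-gene pool covers the
concomitant oncogene variants the panel reports (APC, BAX, KRAS, CDKN2A,
CTNNB1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import ClinvarStatus, Consequence


@dataclass(frozen=True)
class VariantDef:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    consequence: Consequence
    protein_change: str
    in_cosmic: bool = False
    clinvar_status: ClinvarStatus = ClinvarStatus.ABSENT
    population_af: float | None = None
    transactivation_class: str = "unknown"
    gof_evidence: tuple[str, ...] = ()

    @property
    def site(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


_TP53_CHROM = "chr17"
_BASE = 7_571_000


def _snv(i: int, paa: str, cons: Consequence, **kw) -> VariantDef:
    return VariantDef("TP53", _TP53_CHROM, _BASE + 10 * i, "C", "T",
                      cons, paa, **kw)


def _indel(i: int, paa: str, cons: Consequence, ref: str, alt: str, **kw) -> VariantDef:
    return VariantDef("TP53", _TP53_CHROM, _BASE + 10 * i, ref, alt,
                      cons, paa, **kw)


_M = Consequence.MISSENSE
_path = ClinvarStatus.PATHOGENIC

#: The eleven GOF hotspot protein changes (all missense, all catalogued).
GOF_POOL: list[VariantDef] = [
    _snv(i, paa, _M, in_cosmic=True, clinvar_status=_path,
         transactivation_class="nonfunctional",
         gof_evidence=ev)
    for i, (paa, ev) in enumerate([
        ("P151S", ("oncogene_cooperation",)),
        ("Y163C", ("p73_interference",)),
        ("R175H", ("p73_interference", "transactivation_of_repressed_genes",
                   "oncogene_cooperation")),
        ("L194R", ("transactivation_of_repressed_genes",)),
        ("Y220C", ("p73_interference",)),
        ("R248Q", ("p73_interference", "oncogene_cooperation")),
        ("R248W", ("p73_interference", "oncogene_cooperation")),
        ("R273C", ("p73_interference",)),
        ("R273H", ("p73_interference", "transactivation_of_repressed_genes")),
        ("R273L", ("oncogene_cooperation",)),
        ("R282W", ("p73_interference", "oncogene_cooperation")),
    ])
]

#: Non-hotspot missense changes (DBD, tetramerization domain, spacer).
#: A minority carry GOF-assay evidence, exercising evidence promotion;
#: several are ClinVar-pathogenic, as in real unclassified sets.
UNCLASSIFIED_MISSENSE_POOL: list[VariantDef] = [
    _snv(20 + i, paa, _M, in_cosmic=cosmic, clinvar_status=cs,
         transactivation_class=ta, gof_evidence=ev)
    for i, (paa, cosmic, cs, ta, ev) in enumerate([
        ("C135F", True, _path, "nonfunctional", ()),
        ("C141Y", True, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("V157F", True, _path, "nonfunctional", ("p73_interference",)),
        ("R158H", True, ClinvarStatus.OTHER, "nonfunctional", ()),
        ("C176F", True, _path, "nonfunctional", ()),
        ("H179R", True, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("Y205C", False, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("S215I", False, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("C238Y", True, _path, "nonfunctional", ("oncogene_cooperation",)),
        ("S241F", True, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("G245D", True, _path, "nonfunctional", ()),
        ("R280K", False, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("E285K", True, ClinvarStatus.ABSENT, "partially_functional", ()),
        ("R337C", False, ClinvarStatus.ABSENT, "partially_functional", ()),
        ("L344P", False, ClinvarStatus.ABSENT, "nonfunctional", ()),
        ("L93F", False, ClinvarStatus.ABSENT, "functional", ()),
        ("L93R", False, ClinvarStatus.ABSENT, "nonfunctional", ()),
    ])
]

NONSENSE_POOL: list[VariantDef] = [
    _snv(50 + i, paa, Consequence.NONSENSE, in_cosmic=True,
         clinvar_status=_path)
    for i, paa in enumerate(
        ["W146*", "Q192*", "R196*", "E204*", "R213*", "E298*", "R306*", "R342*"])
]

FRAMESHIFT_POOL: list[VariantDef] = [
    _indel(60 + i, paa, Consequence.FRAMESHIFT, "CA", "C",
           in_cosmic=False, clinvar_status=_path)
    for i, paa in enumerate(
        ["S90Pfs*33", "K120Rfs*2", "P152Lfs*18", "T155Nfs*15",
         "A276Gfs*43", "L330Rfs*3"])
]

SPLICE_POOL: list[VariantDef] = [
    _snv(70, "", Consequence.SPLICE_ACCEPTOR, in_cosmic=True),
    _snv(71, "", Consequence.SPLICE_DONOR, in_cosmic=True),
    _snv(72, "", Consequence.SPLICE_REGION, population_af=0.0001),
    _snv(73, "", Consequence.SPLICE_REGION),
]

INFRAME_POOL: list[VariantDef] = [
    _indel(80, "I255del", Consequence.INFRAME_DELETION, "CTTT", "C",
           in_cosmic=True),
]

#: Common germline TP53 polymorphism planted in both tumor and normal
#: samples as a germline contaminant the somatic filter must remove.
GERMLINE_CONTAMINANT = VariantDef(
    "TP53", _TP53_CHROM, _BASE + 900, "G", "C", _M, "P72R",
    population_af=0.55, in_cosmic=False,
)

OTHER_GENE_POOL: list[VariantDef] = [
    VariantDef("APC", "chr5", 112_175_200, "C", "T", Consequence.NONSENSE,
               "R1450*", in_cosmic=True, clinvar_status=_path),
    VariantDef("BAX", "chr19", 49_458_100, "GA", "G", Consequence.FRAMESHIFT,
               "E41Gfs*33", in_cosmic=True),
    VariantDef("KRAS", "chr12", 25_398_284, "C", "T", _M, "G12D",
               in_cosmic=True, clinvar_status=_path),
    VariantDef("CDKN2A", "chr9", 21_971_100, "C", "T", _M, "R24P",
               in_cosmic=False),
    VariantDef("CDKN2A", "chr9", 21_971_140, "C", "T", _M, "A57V",
               in_cosmic=False),
    VariantDef("CDKN2A", "chr9", 21_971_180, "C", "T", _M, "D84N",
               in_cosmic=False),
    VariantDef("CDKN2A", "chr9", 21_971_220, "C", "T", _M, "P114L",
               in_cosmic=True, clinvar_status=_path),
    VariantDef("CTNNB1", "chr3", 41_266_100, "C", "T", _M, "T41A",
               in_cosmic=True, clinvar_status=_path),
    VariantDef("CTNNB1", "chr3", 41_266_140, "C", "T", _M, "S45F",
               in_cosmic=True, clinvar_status=_path),
]

#: Contigs used by the synthetic VCFs, in header order.
CONTIGS: list[tuple[str, int]] = [
    ("chr3", 198_295_559),
    ("chr5", 181_538_259),
    ("chr9", 138_394_717),
    ("chr12", 133_275_309),
    ("chr17", 83_257_441),
    ("chr19", 58_617_616),
]
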