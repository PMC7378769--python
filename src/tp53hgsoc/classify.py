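"""GOF / LOF / unclassified categorization of TP53 variants.

The rule-based scheme:

* **GOF** — missense changes on the oncomorphic hotspot list (eight
  mutations expanded to eleven explicit protein changes: P151S, Y163C,
  R175H, L194R, Y220C, R248Q, R248W, R273C, R273H, R273L, R282W), mutants
  shown experimentally to acquire oncogenic activity.
* **LOF** — nonsense and frameshift variants, which truncate p53 and
  abolish its function.
* **unclassified** — everything else reaching the classifier: non-hotspot
  missense, splice-site/splice-region, stop-lost/start-lost and inframe
  deletions, whose functional impact is not established by the rule.

Functional-assay annotations (transcriptional-activity class and three GOF
activities: interference with p73, transactivation of genes repressed by
wild-type p53, cooperation with oncogenes in cell transformation) are
joined from an IARC-style table when available. An unclassified missense
variant whose mutant shows at least one GOF activity can additionally be
*promoted* to evidence-based GOF; the promotion is reported alongside, and
never overwrites, the rule-based category.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .hgvs import codon_number
from .types import Category, Consequence, VariantCall

logger = logging.getLogger(__name__)

#: p53 domain boundaries (residue ranges, inclusive). Only the spacer/DBD
#: boundary at residue 93 is pinned by the cohort data; the rest follow the
#: canonical p53 domain annotation and can be overridden.
DEFAULT_DOMAIN_BOUNDARIES: dict[str, tuple[int, int]] = {
    "TAD": (1, 61),
    "spacer": (62, 93),
    "DBD": (94, 312),
    "tetramerization": (323, 356),
}

GOF_EVIDENCE_KINDS = (
    "p73_interference",
    "transactivation_of_repressed_genes",
    "oncogene_cooperation",
)

LOF_CONSEQUENCES = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})


@dataclass(frozen=True)
class ClassifiedVariant:
    """A variant call plus its functional category and annotations."""

    call: VariantCall
    category: Category
    transactivation_class: str = "unknown"
    gof_evidence: frozenset[str] = frozenset()
    domain_location: str = "other"
    gof_by_evidence: bool = False  # evidence-based promotion, reported alongside

    @property
    def effective_category(self) -> Category:
        """Category with evidence-based GOF promotion applied."""
        return Category.GOF if self.gof_by_evidence else self.category


def locate_domain(
    protein_change: str,
    boundaries: dict[str, tuple[int, int]] | None = None,
) -> str:
    """Map a protein change to the p53 domain containing its codon."""
    boundaries = boundaries or DEFAULT_DOMAIN_BOUNDARIES
    codon = codon_number(protein_change)
    if codon is None:
        if protein_change:
            logger.warning("unparseable protein change %r -> domain 'other'",
                           protein_change)
        return "other"
    for name, (lo, hi) in boundaries.items():
        if lo <= codon <= hi:
            return name
    return "other"


def classify(
    call: VariantCall,
    gof_list: frozenset[str] | None = None,
    iarc_annotations: pd.DataFrame | None = None,
) -> ClassifiedVariant:
    """Assign the rule-based category and join functional annotations.

    Raises on non-TP53 genes: concomitant oncogene calls are tabulated by
    the cohort module, not categorized here.
    """
    if call.gene != "TP53":
        raise ValueError(f"classify() is TP53-only; got gene {call.gene!r}")
    if gof_list is None:
        from .io import read_gof_list
        gof_list = read_gof_list()

    if call.consequence == Consequence.MISSENSE and call.protein_change in gof_list:
        category = Category.GOF
    elif call.consequence in LOF_CONSEQUENCES:
        category = Category.LOF
    else:
        category = Category.UNCLASSIFIED

    ta_class = "unknown"
    evidence: frozenset[str] = frozenset()
    if iarc_annotations is not None and call.protein_change in iarc_annotations.index:
        row = iarc_annotations.loc[call.protein_change]
        ta_class = str(row["transactivation_class"])
        evidence = frozenset(k for k in GOF_EVIDENCE_KINDS if bool(row[k]))

    return ClassifiedVariant(
        call=call,
        category=category,
        transactivation_class=ta_class,
        gof_evidence=evidence,
        domain_location=locate_domain(call.protein_change),
    )


def promote_by_evidence(cv: ClassifiedVariant) -> ClassifiedVariant:
    """Promote an unclassified missense variant to evidence-based GOF if
    its mutant shows at least one GOF activity.

    The rule-based category is retained; promotion is recorded in
    ``gof_by_evidence``. Calling this on a non-eligible variant (not
    unclassified, or not missense) is a precondition violation.
    """
    if cv.category != Category.UNCLASSIFIED or cv.call.consequence != Consequence.MISSENSE:
        raise ValueError(
            "evidence-based GOF promotion applies only to unclassified "
            f"missense variants; got {cv.category.value} {cv.call.consequence.value}"
        )
    if cv.gof_evidence:
        return replace(cv, gof_by_evidence=True)
    return cv


def classify_cohort(
    calls: list[VariantCall],
    gof_list: frozenset[str] | None = None,
    iarc_annotations: pd.DataFrame | None = None,
    promote: bool = True,
) -> list[ClassifiedVariant]:
    """Classify every TP53 call, applying evidence promotion where eligible."""
    if gof_list is None:
        from .io import read_gof_list
        gof_list = read_gof_list()
    out = []
    for call in calls:
        cv = classify(call, gof_list, iarc_annotations)
        if (promote and cv.category == Category.UNCLASSIFIED
                and cv.call.consequence == Consequence.MISSENSE):
            cv = promote_by_evidence(cv)
        out.append(cv)
    return out


def classified_to_frame(classified: list[ClassifiedVariant]) -> pd.DataFrame:
    """Flatten classified variants to a per-variant DataFrame."""
    rows = []
    for cv in classified:
        c = cv.call
        rows.append({
            "sample_id": c.sample_id, "gene": c.gene, "chrom": c.chrom,
            "pos": c.pos, "ref": c.ref, "alt": c.alt,
            "consequence": c.consequence.value,
            "protein_change": c.protein_change,
            "alt_reads": c.alt_reads, "total_reads": c.total_reads,
            "vaf": c.vaf,
            "category": cv.category.value,
            "effective_category": cv.effective_category.value,
            "gof_by_evidence": cv.gof_by_evidence,
            "transactivation_class": cv.transactivation_class,
            "gof_evidence": ";".join(sorted(cv.gof_evidence)),
            "domain_location": cv.domain_location,
        })
    cols = ["sample_id", "gene", "chrom", "pos", "ref", "alt", "consequence",
            "protein_change", "alt_reads", "total_reads", "vaf", "category",
            "effective_category", "gof_by_evidence", "transactivation_class",
            "gof_evidence", "domain_location"]
    return pd.DataFrame(rows, columns=cols)
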