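"""p53 immunohistochemistry categorization and variant-class concordance.

Staining is scored as the percentage of tumor nuclei with positive p53
staining and categorized High (≥ 70%), Intermediate (> 10% and < 70%) or
Low (≤ 10%); completely absent staining (0%) is split out of the Low
bucket as Negative so the contingency table can distinguish null-pattern
from weak staining. Both overexpression (High) and loss (Low/Negative)
are abnormal patterns suggestive of mutant p53; Intermediate is the
normal, wild-type-like pattern.

Low or absent staining is used as a predictor of p53 loss of function:
sensitivity is the fraction of LOF-variant samples with Low/Negative
staining and specificity the fraction of reference-class samples without
it. Two reference (negative) classes are reported side by side: GOF-only
samples, and all non-LOF variant samples.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging
import math

import pandas as pd

logger = logging.getLogger(__name__)

HIGH, INTERMEDIATE, LOW, NEGATIVE = "High", "Intermediate", "Low", "Negative"
STAINING_CLASSES = (NEGATIVE, HIGH, INTERMEDIATE, LOW)
ABNORMAL_CLASSES = frozenset({HIGH, LOW, NEGATIVE})
LOSS_PATTERN = frozenset({LOW, NEGATIVE})   # the LOF-predictive test

CATEGORY_COLUMNS = ("GOF", "LOF", "unclassified", "wild_type")


def categorize_staining(pct_positive: float) -> str:
    """Staining class for a percentage of positively stained nuclei."""
    if not 0 <= pct_positive <= 100:
        raise ValueError(f"pct_positive outside [0,100]: {pct_positive}")
    if pct_positive == 0:
        return NEGATIVE
    if pct_positive >= 70:
        return HIGH
    if pct_positive <= 10:
        return LOW
    return INTERMEDIATE


@dataclass(frozen=True)
class IHCResult:
    sample_id: str
    pct_positive: float
    staining_class: str
    abnormal: bool

    @classmethod
    def from_pct(cls, sample_id: str, pct_positive: float) -> "IHCResult":
        sc = categorize_staining(pct_positive)
        return cls(sample_id, pct_positive, sc, sc in ABNORMAL_CLASSES)


def sample_category(categories: list[str],
                    precedence: tuple[str, ...] = ("GOF", "LOF", "unclassified")) -> str:
    """Collapse a sample's variant categories to one label for the
    concordance table (default precedence GOF > LOF > unclassified)."""
    for cat in precedence:
        if cat in categories:
            return cat
    return categories[0]


def concordance_table(
    ihc: pd.DataFrame,
    classified: pd.DataFrame,
    wild_type_samples: set[str] | None = None,
    precedence: tuple[str, ...] = ("GOF", "LOF", "unclassified"),
) -> pd.DataFrame:
    """Contingency table of staining class × sample-level variant category.

    ``ihc`` needs columns sample_id, pct_positive; ``classified`` needs
    sample_id, category. Samples with several TP53 variants take the
    highest-precedence category. IHC-tested samples with no variant record
    are counted under wild_type only when listed in ``wild_type_samples``
    (an asserted TP53-wild-type set); otherwise they are dropped with a
    warning.
    """
    wild_type_samples = wild_type_samples or set()
    per_sample = (classified.groupby("sample_id")["category"]
                  .apply(lambda s: sample_category(list(s), precedence)))
    table = pd.DataFrame(0, index=list(STAINING_CLASSES),
                         columns=list(CATEGORY_COLUMNS))
    for row in ihc.itertuples(index=False):
        sid = str(row.sample_id)
        sc = categorize_staining(float(row.pct_positive))
        if sid in per_sample.index:
            cat = per_sample.loc[sid]
        elif sid in wild_type_samples:
            cat = "wild_type"
        else:
            logger.warning("IHC sample %r has no variant record and is not "
                           "asserted wild-type; dropped", sid)
            continue
        table.loc[sc, cat] += 1
    return table


@dataclass(frozen=True)
class LofPredictiveMetrics:
    """Low/absent staining as a predictor of loss of p53 function."""

    sensitivity: float             # P(Low/Negative | LOF)
    specificity_gof: float         # P(not Low/Negative | GOF)
    specificity_non_lof: float     # P(not Low/Negative | any non-LOF variant)
    n_lof: int
    n_gof: int
    n_non_lof: int


def lof_predictive_metrics(contingency: pd.DataFrame) -> LofPredictiveMetrics:
    """Sensitivity/specificity of the Low-or-Negative staining test for
    LOF variants, from a staining × category contingency table.

    A zero-count reference class leaves the metric undefined (NaN).
    """
    lof_total = int(contingency["LOF"].sum())
    lof_pos = int(contingency.loc[list(LOSS_PATTERN), "LOF"].sum())
    gof_total = int(contingency["GOF"].sum())
    gof_neg = gof_total - int(contingency.loc[list(LOSS_PATTERN), "GOF"].sum())
    non_lof_cols = [c for c in ("GOF", "unclassified") if c in contingency.columns]
    non_lof_total = int(contingency[non_lof_cols].sum().sum())
    non_lof_pos = int(contingency.loc[list(LOSS_PATTERN), non_lof_cols].sum().sum())
    return LofPredictiveMetrics(
        sensitivity=lof_pos / lof_total if lof_total else math.nan,
        specificity_gof=gof_neg / gof_total if gof_total else math.nan,
        specificity_non_lof=(non_lof_total - non_lof_pos) / non_lof_total
        if non_lof_total else math.nan,
        n_lof=lof_total, n_gof=gof_total, n_non_lof=non_lof_total,
    )
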