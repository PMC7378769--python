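import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tp53hgsoc.simulate import SimParams, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


# Published contingency table of p53 staining class vs variant category
# (68 IHC-tested samples).
TABLE2 = pd.DataFrame(
    {
        "GOF": [4, 11, 0, 0],
        "LOF": [8, 0, 0, 1],
        "unclassified": [22, 6, 9, 3],
        "wild_type": [2, 0, 1, 1],
    },
    index=["Negative", "High", "Intermediate", "Low"],
)

# Published per-type variant counts (BRCA1 + BRCA2 columns summed).
TABLE1_TYPE_COUNTS = {
    "missense": 58,      # 47 + 11
    "frameshift": 15,    # 11 + 4
    "nonsense": 15,      # 13 + 2
    "other": 7,          # 4 + 3; splice sites (3), splice regions (3), inframe (1)
}

REFERENCE_LOF = (261, 1249)


def build_table1_cohort() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reconstruct a per-variant classified frame and patient metadata
    matching the published per-type counts: one variant per patient,
    99 enrolled patients of whom 95 carry a TP53 variant (22 GOF
    hotspot missense among the 58 missense)."""
    gof_changes = ["P151S", "Y163C", "R175H", "L194R", "Y220C", "R248Q",
                   "R248W", "R273C", "R273H", "R273L", "R282W"] * 2
    rows = []
    i = 0

    def add(consequence, category, protein_change=""):
        nonlocal i
        i += 1
        rows.append({
            "sample_id": f"P{i:03d}", "gene": "TP53", "chrom": "chr17",
            "pos": 7_571_000 + i, "ref": "C", "alt": "T",
            "consequence": consequence, "protein_change": protein_change,
            "category": category,
        })

    for paa in gof_changes:                      # 22 GOF missense
        add("missense", "GOF", paa)
    for _ in range(TABLE1_TYPE_COUNTS["missense"] - 22):
        add("missense", "unclassified", "L257Q")
    for _ in range(TABLE1_TYPE_COUNTS["frameshift"]):
        add("frameshift", "LOF", "T155Nfs*15")
    for _ in range(TABLE1_TYPE_COUNTS["nonsense"]):
        add("nonsense", "LOF", "R213*")
    for cons in ["splice_acceptor", "splice_donor", "splice_acceptor",
                 "splice_region", "splice_region", "splice_region",
                 "inframe_deletion"]:             # 7 "other"
        add(cons, "unclassified")

    classified = pd.DataFrame(rows)
    meta = pd.DataFrame({
        "sample_id": [f"P{j:03d}" for j in range(1, 100)],
        "tumor_cell_pct": 60.0,
        "brca_gene": ["BRCA1"] * 78 + ["BRCA2"] * 21,
    })
    return classified, meta


@pytest.fixture(scope="session")
def table1_cohort():
    return build_table1_cohort()


@pytest.fixture(scope="session")
def table2_contingency():
    return TABLE2.copy()


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A 40-patient simulated cohort written to disk once per session."""
    out = tmp_path_factory.mktemp("sim_small")
    cohort = simulate_cohort(SimParams(n_patients=40), seed=11, out_dir=out)
    return cohort, out


@pytest.fixture(scope="session")
def sim_full(tmp_path_factory):
    """A full-size (99-patient) cohort under default study conditions."""
    out = tmp_path_factory.mktemp("sim_full")
    cohort = simulate_cohort(SimParams(), seed=23, out_dir=out)
    return cohort, out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
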