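"""Somatic variant-retention rules."""

import itertools

import pytest
from hypothesis import given
from hypothesis import strategies as st

from tp53hgsoc.filtering import (
    DISRUPTIVE_CONSEQUENCES,
    RARE_ADMITTED_CONSEQUENCES,
    FilterParams,
    admit_by_type,
    filter_somatic,
)
from tp53hgsoc.types import ClinvarStatus, Consequence, VariantCall


def _call(sample="S1", alt_reads=100, total=1000, cons=Consequence.MISSENSE,
          popaf=None, cosmic=False, clinvar=ClinvarStatus.ABSENT, pos=100):
    return VariantCall(sample, "TP53", "chr17", pos, "C", "T", cons, "",
                       alt_reads, total, population_af=popaf,
                       in_cosmic=cosmic, clinvar_status=clinvar)


class TestExamples:
    def test_low_alt_reads_rejected(self):
        res = filter_somatic([_call(alt_reads=5, total=50)], [],
                             allow_missing_normal=True)
        assert not res.kept
        assert res.rejected[0].reason == "min_alt_reads"

    def test_low_vaf_rejected(self):
        res = filter_somatic([_call(alt_reads=30, total=1000)], [],
                             allow_missing_normal=True)
        assert res.rejected[0].reason == "min_vaf"

    def test_germline_rejected_when_in_normal(self):
        tumor = _call(alt_reads=400, total=1000)
        normal = _call(alt_reads=450, total=1000)
        res = filter_somatic([tumor], [normal])
        assert res.rejected[0].reason == "germline"

    def test_normal_below_cutoff_does_not_flag_germline(self):
        tumor = _call(alt_reads=400, total=1000)
        normal = _call(alt_reads=100, total=1000)  # 10% < 20%
        res = filter_somatic([tumor], [normal])
        assert res.kept == [tumor]

    def test_missing_matched_normal_is_an_error(self):
        with pytest.raises(ValueError, match="no matched normal"):
            filter_somatic([_call()], [], normal_samples=set())

    def test_boundaries_are_inclusive(self):
        # exactly 6 alt reads and exactly 5% VAF are kept
        res = filter_somatic([_call(alt_reads=6, total=120)], [],
                             allow_missing_normal=True)
        assert res.kept


class TestAdmitByType:
    def test_frameshift_admitted_regardless_of_popaf(self):
        ok, reason = admit_by_type(_call(cons=Consequence.FRAMESHIFT, popaf=0.02))
        assert ok and reason == "disruptive_consequence"

    def test_common_missense_rejected(self):
        ok, reason = admit_by_type(_call(popaf=0.006))
        assert not ok and reason == "variant_type"

    def test_synonymous_admitted_only_via_catalogues(self):
        syn = _call(cons=Consequence.SYNONYMOUS)
        assert not admit_by_type(syn)[0]
        assert admit_by_type(_call(cons=Consequence.SYNONYMOUS,
                                   clinvar=ClinvarStatus.PATHOGENIC))[0]
        assert admit_by_type(_call(cons=Consequence.SYNONYMOUS, cosmic=True))[0]

    def test_absent_popaf_passes_rare_rule(self):
        assert admit_by_type(_call(popaf=None))[1] == "rare_missense_or_splice_region"

    def test_against_brute_force_disjunction(self):
        """Exhaustively compare against a literal evaluation of the four
        published admission rules."""
        for cons, popaf, cosmic, clinvar in itertools.product(
                Consequence,
                [None, 0.0, 0.004, 0.005, 0.02],
                [False, True],
                ClinvarStatus):
            call = _call(cons=cons, popaf=popaf, cosmic=cosmic, clinvar=clinvar)
            rule1 = cons in DISRUPTIVE_CONSEQUENCES
            rule2 = (cons in RARE_ADMITTED_CONSEQUENCES
                     and (popaf is None or popaf < 0.005))
            rule3 = cosmic
            rule4 = clinvar in (ClinvarStatus.PATHOGENIC,
                                ClinvarStatus.LIKELY_PATHOGENIC)
            assert admit_by_type(call)[0] == (rule1 or rule2 or rule3 or rule4)


call_strategy = st.builds(
    _call,
    sample=st.sampled_from(["S1", "S2", "S3"]),
    total=st.integers(50, 3000),
    alt_reads=st.integers(0, 49),  # bounded below total's minimum
    cons=st.sampled_from(list(Consequence)),
    popaf=st.one_of(st.none(), st.floats(0, 0.05)),
    cosmic=st.booleans(),
    clinvar=st.sampled_from(list(ClinvarStatus)),
    pos=st.integers(1, 500),
)


@given(st.lists(call_strategy, max_size=40),
       st.lists(call_strategy, max_size=10))
def test_partition_and_idempotence(tumor, normal):
    """kept ∪ rejected partitions the input exactly; refiltering the kept
    set keeps everything (idempotence)."""
    res = filter_somatic(tumor, normal, allow_missing_normal=True)
    assert len(res.kept) + len(res.rejected) == len(tumor)
    assert sorted(id(c) for c in res.kept + [r.call for r in res.rejected]) \
        == sorted(id(c) for c in tumor)
    again = filter_somatic(res.kept, normal, allow_missing_normal=True)
    assert again.kept == res.kept and not again.rejected
    # every rejection carries exactly one known reason code
    valid = {"min_alt_reads", "min_vaf", "germline", "variant_type"}
    assert all(r.reason in valid for r in res.rejected)


@given(st.integers(0, 2**31 - 1))
def test_planted_germline_never_survives(seed):
    """A variant present in the matched normal at VAF >= 20% never passes,
    whatever its tumor-side support."""
    import numpy as np
    rng = np.random.default_rng(seed)
    tumor, normal = [], []
    for i in range(20):
        depth = int(rng.integers(100, 2000))
        alt = int(rng.integers(6, depth))
        tumor.append(_call(alt_reads=alt, total=depth, pos=i + 1))
        ndepth = int(rng.integers(100, 2000))
        nalt = int(rng.integers(int(np.ceil(0.2 * ndepth)), ndepth + 1))
        normal.append(_call(alt_reads=nalt, total=ndepth, pos=i + 1))
    res = filter_somatic(tumor, normal)
    assert not res.kept
    kept_reasons = {r.reason for r in res.rejected}
    assert kept_reasons <= {"germline", "min_vaf", "min_alt_reads"}


def test_custom_params_respected():
    params = FilterParams(min_alt_reads=10, min_tumor_vaf=0.10)
    res = filter_somatic([_call(alt_reads=8, total=60)], [],
                         params, allow_missing_normal=True)
    assert res.rejected[0].reason == "min_alt_reads"
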