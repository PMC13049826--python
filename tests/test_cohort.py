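"""Encoded deficiency cohort and the donor screen cohort."""

from collections import Counter

import pytest

from haplotile.cohort import SV_HGVS_C, make_cohort, make_table2_cohort
from haplotile.variants import apply_variants, parse_hgvs


def test_cohort_composition(cohort):
    assert len(cohort) == 43
    groups = Counter(s.group for s in cohort)
    assert groups == {"I": 14, "II": 29}
    assert sum(2 for _ in cohort) == 86  # 28 + 58 haplotypes


def test_key_genotypes(by_id):
    # homozygous 12-bp deletion
    i11 = by_id["I-11"]
    assert i11.hap1_variants == i11.hap2_variants == ("c.1228_1239delATTGTGCCTATT",)
    assert i11.hap1_seq == i11.hap2_seq
    # variant-free sample
    assert by_id["II-23"].hap1_variants == () and by_id["II-23"].hap2_variants == ()
    # structural-variant carriers: three type I, one type II
    carriers = [s.sample_id for s in by_id.values() if s.is_sv_carrier]
    assert sorted(carriers) == ["I-12", "I-13", "I-14", "II-22"]


def test_sequences_derive_from_variant_lists(locus, by_id):
    s = by_id["I-07"]
    vs = [parse_hgvs(n, locus.transcript, locus.reference) for n in s.hap1_variants]
    seq, _ = apply_variants(locus.reference, vs)
    assert seq == s.hap1_seq
    sv = by_id["I-12"]
    assert len(sv.hap1_seq) == locus.reference.length - 19_971 + 16


def test_marker_panel_leaves_truth_unchanged(cohort, marked_cohort):
    for plain, marked in zip(cohort, marked_cohort):
        assert plain.hap1_variants == marked.hap1_variants
        assert plain.hap2_variants == marked.hap2_variants
        assert marked.hap2_extra  # markers present on haplotype 2


def test_donor_cohort_truth_counts(locus):
    co = make_cohort(locus, n=600, n_carriers=3, seed=5)
    assert co.n == 600
    assert len(co.carrier_ids) == 3
    for d in co.donors:
        if d.sample_id in co.carrier_ids:
            assert (SV_HGVS_C in d.hap1_variants) != (SV_HGVS_C in d.hap2_variants)
        else:
            assert SV_HGVS_C not in d.hap1_variants + d.hap2_variants


def test_donor_cohort_edge_cases(locus):
    none = make_cohort(locus, n=20, n_carriers=0, seed=1, background_snvs=False)
    assert len(none.carrier_ids) == 0
    allc = make_cohort(locus, n=10, n_carriers=10, seed=1, background_snvs=False)
    assert len(allc.carrier_ids) == 10
    with pytest.raises(ValueError):
        make_cohort(locus, n=5, n_carriers=6)


def test_donor_cohort_deterministic(locus):
    a = make_cohort(locus, n=50, n_carriers=2, seed=9)
    b = make_cohort(locus, n=50, n_carriers=2, seed=9)
    assert a.carrier_ids == b.carrier_ids
    assert all(
        x.hap1_variants == y.hap1_variants and x.hap2_seq == y.hap2_seq
        for x, y in zip(a.donors, b.donors)
    )
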