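"""Haplotype diffing, reportability filter, zygosity and cohort spectrum."""

from collections import Counter

import pytest

from haplotile.calling import (
    DiffError,
    annotate,
    call_haplotype,
    classify_zygosity,
    diff_haplotype,
    filter_reportable,
    tabulate_spectrum,
)
from haplotile.cohort import SV_HGVS_C
from haplotile.variants import Variant, VariantKind, apply_variants, parse_hgvs


def test_identical_sequence_diffs_empty(locus):
    assert diff_haplotype(locus.reference.sequence, locus.reference) == []


def test_single_reportable_snv_recovered(locus, by_id):
    """The c.380C>T haplotype diffs to exactly that one reportable call."""
    s = by_id["I-07"]
    _all_calls, reportable = call_haplotype(s.hap1_seq, locus)
    assert [c.hgvs_c for c in reportable] == ["c.380C>T"]


def test_sv_haplotype_diffs_to_one_delins(locus, by_id):
    vs = diff_haplotype(by_id["I-12"].hap1_seq, locus.reference)
    assert len(vs) == 1
    v = vs[0]
    assert v.kind is VariantKind.DELINS
    assert len(v.ref) == 19_971 and v.alt == "CCAATGCTAAGGTTGA"
    # applying the call reproduces the haplotype exactly
    seq, _ = apply_variants(locus.reference, vs)
    assert seq == by_id["I-12"].hap1_seq


def test_diff_applies_back_for_multivariant_haplotypes(locus, by_id):
    s = by_id["I-04"]  # c.332_333delCA + c.-132A>C
    vs = diff_haplotype(s.hap1_seq, locus.reference)
    seq, _ = apply_variants(locus.reference, vs)
    assert seq == s.hap1_seq


def test_diff_rejects_garbage(locus):
    with pytest.raises(DiffError):
        diff_haplotype("ACGT" * 100, locus.reference)


def test_reportability_rules(locus):
    t, ref = locus.transcript, locus.reference

    def call(name):
        return annotate(parse_hgvs(name, t, ref), locus)

    kept = filter_reportable([call("c.609+7A>G")])
    assert len(kept) == 1  # intronic, 7 bp from the boundary

    utr = filter_reportable([call("c.-132A>C")])
    assert len(utr) == 1  # 5'UTR

    deep_pos = 25_000  # deep in intron 1
    deep = annotate(Variant(deep_pos, ref.base(deep_pos), "A"
                            if ref.base(deep_pos) != "A" else "C"), locus)
    assert filter_reportable([deep]) == []

    sv = annotate(locus.sv_truth, locus)
    assert sv.is_structural
    assert filter_reportable([sv]) == [sv]  # structural calls always kept


@pytest.mark.parametrize(
    "sid, expected",
    [
        ("I-11", "homozygous"),
        ("I-12", "compound_heterozygous"),
        ("I-01", "compound_heterozygous"),
        ("II-05", "single_heterozygous"),
        ("II-23", "none"),
    ],
)
def test_zygosity_examples(by_id, sid, expected):
    s = by_id[sid]
    z = classify_zygosity(sid, s.group, s.hap1_variants, s.hap2_variants)
    assert z.zygosity == expected


def _truth_hap_calls(cohort):
    return [
        (s.sample_id, s.group, names)
        for s in cohort
        for names in (s.hap1_variants, s.hap2_variants)
    ]


def test_spectrum_counts_and_frequencies(locus, cohort):
    spec = tabulate_spectrum(_truth_hap_calls(cohort), locus)
    assert spec.n_hap_i == 28 and spec.n_hap_ii == 58
    assert spec.variant_counts[("c.-132A>C", "I")] == 9
    assert spec.variant_counts[("c.-132A>C", "II")] == 12
    assert spec.variant_counts[(SV_HGVS_C, "I")] == 3
    assert spec.variant_counts[(SV_HGVS_C, "II")] == 1
    assert spec.variant_counts[("c.1228_1239delATTGTGCCTATT", "I")] == 9
    # frequencies are recomputed from counts, never stored
    df = spec.per_variant
    assert (df["freq_I"] == df["count_I"] / 28).all()
    assert (df["freq_II"] == df["count_II"] / 58).all()


def test_spectrum_signature_rows(locus, cohort):
    """The signature table (promoter SNV excluded) has 18 distinct rows."""
    spec = tabulate_spectrum(_truth_hap_calls(cohort), locus)
    assert len(spec.signatures) == 18


def test_cohort_zygosity_tallies(cohort):
    zyg = [
        classify_zygosity(s.sample_id, s.group, s.hap1_variants, s.hap2_variants)
        for s in cohort
    ]
    counts = Counter((z.group, z.zygosity) for z in zyg)
    assert counts[("I", "compound_heterozygous")] == 13
    assert counts[("I", "homozygous")] == 1
    # type II: 4 samples with variants on both haplotypes, 18 on one, 7 none
    assert counts[("II", "compound_heterozygous")] == 4
    assert counts[("II", "single_heterozygous")] == 18
    assert counts[("II", "none")] == 7
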