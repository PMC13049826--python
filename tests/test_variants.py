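"""HGVS parsing/naming, indel normalization and variant application."""

import re

import pytest
from hypothesis import given, settings, strategies as st

from haplotile.variants import (
    HGVSParseError,
    Variant,
    VariantConflictError,
    apply_variants,
    five_prime_alias,
    format_hgvs_c,
    format_hgvs_g,
    normalize_variant,
    parse_hgvs,
)

PRINTED_FORMS = [
    "c.-132A>C",
    "c.220C>T",
    "c.332_333delCA",
    "c.429+3insG",
    "c.430-1G>C",
    "c.430-2A>G",
    "c.609+7A>G",
    "c.1006+2T>G",
    "c.1156C>T",
    "c.1228_1239delATTGTGCCTATT",
    "c.1340_1343dupTCTT",
]


@pytest.mark.parametrize("text", PRINTED_FORMS)
def test_parse_name_round_trip(locus, text):
    """parse(name(v)) applied to the reference reproduces the same edit."""
    t, ref = locus.transcript, locus.reference
    v = parse_hgvs(text, t, ref)
    name = format_hgvs_c(v, t, ref)
    v2 = parse_hgvs(name, t, ref)
    s1, _ = apply_variants(ref, [v])
    s2, _ = apply_variants(ref, [v2])
    assert s1 == s2
    # naming is stable under a second round
    assert format_hgvs_c(v2, t, ref) == name


def test_parse_tolerates_printed_spacing(locus):
    t, ref = locus.transcript, locus.reference
    assert parse_hgvs("c.-132 A > C", t, ref) == parse_hgvs("c.-132A>C", t, ref)
    assert parse_hgvs("c.609 + 7 A > G", t, ref) == parse_hgvs("c.609+7A>G", t, ref)


def test_parse_large_delins_forms(locus):
    t, ref = locus.transcript, locus.reference
    v = parse_hgvs("c.1-15966_c.120+3885delinsCCAATGCTAAGGTTGA", t, ref)
    assert len(v.ref) == 19_971
    assert v.alt == "CCAATGCTAAGGTTGA" and len(v.alt) == 16
    # g-space form with a repeated g. prefix parses too
    g = parse_hgvs("g.25000_g.44970delinsCCAATGCTAAGGTTGA", t, ref)
    assert g == v


def test_single_position_multibase_del_alias(locus):
    """The printed c.1227delTATTGTGCCTAT and c.1228_1239delATTGTGCCTATT are
    the same edit in a repeat context and normalize identically."""
    t, ref = locus.transcript, locus.reference
    a = parse_hgvs("c.1227delTATTGTGCCTAT", t, ref)
    b = parse_hgvs("c.1228_1239delATTGTGCCTATT", t, ref)
    sa, _ = apply_variants(ref, [a])
    sb, _ = apply_variants(ref, [b])
    assert sa == sb  # byte-for-byte identical edited sequences
    assert normalize_variant(a, ref) == normalize_variant(b, ref)
    assert format_hgvs_c(normalize_variant(a, ref), t, ref) == "c.1228_1239delATTGTGCCTATT"
    # the 5'-most alias is the other printed form
    alias = five_prime_alias(b, ref)
    assert alias.pos == normalize_variant(b, ref).pos - 1


def test_homopolymer_deletion_placements_normalize_identically(locus):
    ref = locus.reference
    m = re.search(r"A{5}(?!A)", ref.sequence)
    assert m, "reference should contain an A homopolymer"
    start = m.start() + 1
    edited = set()
    norms = set()
    for k in range(5):
        v = Variant(pos=start + k, ref="A", alt="")
        edited.add(apply_variants(ref, [v])[0])
        norms.add(normalize_variant(v, ref))
    assert len(edited) == 1  # all placements give one edited string
    assert len(norms) == 1   # and one canonical variant


def test_normalization_idempotent_and_snv_fixed_point(locus):
    ref = locus.reference
    snv = Variant(pos=5000, ref=ref.base(5000), alt="A" if ref.base(5000) != "A" else "G")
    assert normalize_variant(snv, ref) == snv
    d = parse_hgvs("c.1227delTATTGTGCCTAT", locus.transcript, ref)
    n1 = normalize_variant(d, ref)
    assert normalize_variant(n1, ref) == n1


def test_apply_variants_lengths_and_map(locus):
    ref = locus.reference
    hap, cmap = apply_variants(ref, [])
    assert hap == ref.sequence
    assert cmap(1) == 1 and cmap(ref.length) == ref.length

    sv = locus.sv_truth
    hap, cmap = apply_variants(ref, [sv])
    assert len(hap) == ref.length - 19_971 + 16
    # map is monotone over unedited positions and -1 inside the deletion
    assert cmap(sv.pos - 1) == sv.pos - 1
    assert cmap(sv.pos + 100) == -1
    assert cmap(sv.end + 1) == sv.pos - 1 + 16 + 1


def test_overlapping_variants_rejected(locus):
    ref = locus.reference
    a = Variant(pos=1000, ref=ref.slice(1000, 1009), alt="")
    b = Variant(pos=1005, ref=ref.base(1005), alt="A" if ref.base(1005) != "A" else "C")
    with pytest.raises(VariantConflictError):
        apply_variants(ref, [a, b])


def test_reference_mismatch_and_bad_syntax(locus):
    ref = locus.reference
    bad = Variant(pos=1000, ref="NOPE", alt="")
    with pytest.raises(VariantConflictError):
        normalize_variant(bad, ref)
    with pytest.raises(HGVSParseError):
        parse_hgvs("c.12inv", locus.transcript, ref)


@st.composite
def random_variant(draw):
    kind = draw(st.sampled_from(["snv", "del", "ins", "dup"]))
    pos = draw(st.integers(min_value=2_000, max_value=70_000))
    length = draw(st.integers(min_value=1, max_value=12))
    alt = "".join(draw(st.lists(st.sampled_from("ACGT"), min_size=1, max_size=8)))
    return kind, pos, length, alt


@given(random_variant())
@settings(max_examples=150, deadline=None, derandomize=True)
def test_fuzzed_hgvs_round_trip(locus, rv):
    """For arbitrary variants: parse(name(v)) reproduces the edit, and
    normalization is idempotent."""
    kind, pos, length, alt = rv
    ref = locus.reference
    t = locus.transcript
    if kind == "snv":
        b = ref.base(pos)
        v = Variant(pos=pos, ref=b, alt="ACGT"[("ACGT".index(b) + 1) % 4])
    elif kind == "del":
        v = Variant(pos=pos, ref=ref.slice(pos, pos + length - 1), alt="")
    elif kind == "ins":
        v = Variant(pos=pos, ref="", alt=alt)
    else:  # duplication of the preceding reference run
        seg = ref.slice(pos - length + 1, pos)
        v = Variant(pos=pos, ref="", alt=seg)
    n = normalize_variant(v, ref)
    assert normalize_variant(n, ref) == n
    name = format_hgvs_c(n, t, ref)
    back = parse_hgvs(name, t, ref)
    s1, _ = apply_variants(ref, [v])
    s2, _ = apply_variants(ref, [back])
    assert s1 == s2
    # g-space naming round-trips as well
    gname = format_hgvs_g(n, ref)
    s3, _ = apply_variants(ref, [parse_hgvs(gname, t, ref)])
    assert s3 == s1
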