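"""Synthetic locus generator, in-silico PCR and read simulation."""

import numpy as np
import pytest

from haplotile.pcr import Dropout, PCRProduct, find_primer_sites, revcomp, simulate_amplicon
from haplotile.simulate import (
    AMPLICON_ERROR_MODEL,
    ErrorModel,
    GAP_CONTROL_PAIR,
    GAP_DELETION_PAIR,
    LR_PRIMERS,
    _mutate,
    build_reference_locus,
    simulate_reads,
    simulate_wgs_reads,
)


def test_locus_dimensions_and_panel(locus):
    assert 74_000 <= locus.reference.length <= 80_000
    panel = locus.panel
    assert len(panel) == 4
    assert [a.length for a in panel] == [20_600, 22_000, 20_600, 23_000]
    assert all(ov >= 3_000 for ov in panel.overlaps)


def test_every_primer_site_unique(locus):
    seq = locus.reference.sequence
    for pair in LR_PRIMERS + (GAP_DELETION_PAIR, GAP_CONTROL_PAIR):
        assert len(find_primer_sites(seq, pair.forward)) == 1
        assert len(find_primer_sites(seq, revcomp(pair.reverse))) == 1
    # the gap-PCR forward primer as printed, found exactly once
    assert find_primer_sites(seq, "GTGTCAAACTGTCATCGGGGTG") != []


def test_generator_determinism():
    a = build_reference_locus(seed=3)
    b = build_reference_locus(seed=3)
    c = build_reference_locus(seed=4)
    assert a.reference.sequence == b.reference.sequence
    assert a.reference.sequence != c.reference.sequence


def test_wild_type_amplicon_products(locus):
    wt = locus.reference.sequence
    lengths = [
        simulate_amplicon(wt, a.pair, locus.lr_max_product).length
        for a in locus.panel
    ]
    assert lengths == [20_600, 22_000, 20_600, 23_000]


def test_sv_haplotype_drops_internal_amplicons(locus, by_id):
    sv_hap = by_id["I-12"].hap1_seq
    results = [
        simulate_amplicon(sv_hap, a.pair, locus.lr_max_product)
        for a in locus.panel
    ]
    assert isinstance(results[0], PCRProduct)
    assert isinstance(results[3], PCRProduct)
    assert isinstance(results[1], Dropout) and results[1].reason == "missing_site"
    assert isinstance(results[2], Dropout) and results[2].reason == "missing_site"


def test_gap_pcr_geometry(locus, by_id):
    wt = locus.reference.sequence
    # wild-type allele: ~20.8 kb product, unamplifiable at short extension
    long_run = simulate_amplicon(wt, locus.gap_assay.deletion_pair, 25_000)
    assert long_run.length == 20_787
    short_run = simulate_amplicon(wt, locus.gap_assay.deletion_pair, 2_000)
    assert isinstance(short_run, Dropout) and short_run.reason == "oversize"
    # deletion allele: the diagnostic band
    band = simulate_amplicon(
        by_id["I-12"].hap1_seq, locus.gap_assay.deletion_pair, 2_000
    )
    assert band.length == 832
    control = simulate_amplicon(wt, locus.gap_assay.control_pair, 2_000)
    assert control.length == 333


def test_error_model_bounds():
    with pytest.raises(ValueError):
        ErrorModel(0.5, 0, 0, 8000, 2000)


def test_error_free_reads_are_exact_substrings(locus):
    product = simulate_amplicon(
        locus.reference.sequence, locus.panel.amplicons[0].pair, 25_000
    )
    model = ErrorModel(0, 0, 0, 4_000, 500)
    reads = simulate_reads(product, depth=3, error_model=model, rng=11)
    for r in reads:
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        assert seq in product.sequence
        assert seq == product.sequence[r.template_start - 1 : r.template_end]


def test_substitution_rate_recovered(locus):
    """Observed mismatch fraction matches the model within binomial noise."""
    rng = np.random.default_rng(5)
    model = ErrorModel(0.02, 0.0, 0.0, 8_000, 2_000)
    template = locus.reference.sequence[:100_000] or locus.reference.sequence
    mutated = _mutate(locus.reference.sequence[:50_000] * 2, model, rng)
    src = locus.reference.sequence[:50_000] * 2
    mism = sum(1 for a, b in zip(src, mutated) if a != b)
    assert len(mutated) == len(src)  # substitutions only
    assert abs(mism / len(src) - 0.02) < 0.005


def test_read_count_scales_with_depth(locus):
    product = simulate_amplicon(
        locus.reference.sequence, locus.panel.amplicons[0].pair, 25_000
    )
    reads = simulate_reads(product, depth=30, rng=1)
    expect = 30 * product.length / AMPLICON_ERROR_MODEL.read_length_mean
    assert abs(len(reads) - expect) <= 1


def test_wgs_reads_cover_both_alleles(locus, by_id):
    s = by_id["I-13"]  # heterozygous structural-variant carrier
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=2)
    haps = [r.haplotype for r in reads]
    frac_h1 = haps.count("H1") / len(haps)
    assert 0.4 <= frac_h1 <= 0.6  # allele balance at depth 30
    # junction-spanning reads (drawn over the SV haplotype junction) exist
    junction = s.hap1_seq.find(locus.sv_truth.alt)
    spanning = [
        r for r in reads
        if r.haplotype == "H1"
        and r.template_start <= junction - 100
        and r.template_end >= junction + len(locus.sv_truth.alt) + 100
    ]
    assert spanning, "expected junction-spanning reads at depth 30"
    assert any(r.haplotype == "H2" for r in reads)


def test_wgs_zero_error_reads_exact(locus, by_id):
    s = by_id["II-23"]
    model = ErrorModel(0, 0, 0, 12_000, 3_000)
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=10, error_model=model, rng=3)
    for r in reads[:20]:
        seq = r.sequence if r.strand == "+" else revcomp(r.sequence)
        assert seq in (s.hap1_seq if r.haplotype == "H1" else s.hap2_seq)
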