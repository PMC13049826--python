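"""Split-read junction calling, coverage profiling, false-positive control."""

import numpy as np
import pytest

from haplotile.cohort import build_sample
from haplotile.simulate import WGS_ERROR_MODEL, simulate_wgs_reads
from haplotile.sv import (
    LowSupportSV,
    call_structural_variants,
    coverage_profile,
    find_junctions,
    map_reads,
    resolve_junction,
)
from haplotile.variants import parse_hgvs

TRUTH_LEFT, TRUTH_RIGHT = 24_999, 44_971  # last/first retained base


def test_exact_recovery_over_seeded_replicates(locus, by_id):
    """Breakpoints and insert recovered exactly (+-0) in 20 replicates at
    depth 30 and HiFi-like error."""
    s = by_id["I-13"]
    for rep in range(20):
        reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30,
                                   rng=1_000 + rep, sample_id="rep")
        calls, _ = call_structural_variants(reads, locus)
        assert len(calls) == 1, f"replicate {rep}"
        c = calls[0]
        assert (c.left, c.right) == (TRUTH_LEFT, TRUTH_RIGHT)
        assert c.deleted_length == 19_971
        assert c.insert == "CCAATGCTAAGGTTGA"
        assert c.zygosity == "het"
        assert c.support >= 3


def test_hgvs_round_trip_of_the_call(locus, by_id):
    s = by_id["I-13"]
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=7)
    calls, _ = call_structural_variants(reads, locus)
    c = calls[0]
    for name in (c.hgvs_g, c.hgvs_c):
        v = parse_hgvs(name, locus.transcript, locus.reference)
        assert v.pos == c.left + 1
        assert v.pos + len(v.ref) - 1 == c.right - 1
        assert v.alt == c.insert
    assert c.hgvs_c == "c.1-15966_c.120+3885delinsCCAATGCTAAGGTTGA"


def test_homozygous_carrier_called_hom(locus):
    from haplotile.cohort import SV_HGVS_C

    hom = build_sample(locus, "HOM", "x", (SV_HGVS_C,), (SV_HGVS_C,))
    reads = simulate_wgs_reads(hom.hap1_seq, hom.hap2_seq, depth=30, rng=9)
    calls, mappings = call_structural_variants(reads, locus)
    assert calls[0].zygosity == "hom"
    cov = coverage_profile(mappings, locus.reference.length)
    assert cov.mean_over(27_000, 43_000) < 1.0  # no coverage in the deletion


def test_no_junctions_on_wild_type(locus, by_id):
    s = by_id["II-23"]
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=10)
    mappings = map_reads(reads, locus)
    assert find_junctions(mappings) == []


def test_small_deletion_below_sv_floor_ignored(locus):
    """A 20-bp deletion is small-variant territory, not an SV junction."""
    ref = locus.reference
    small = f"g.30000_30019del{ref.slice(30000, 30019)}"
    s = build_sample(locus, "SMALL", "x", (small,), ())
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=11)
    mappings = map_reads(reads, locus)
    assert find_junctions(mappings) == []


def test_low_support_flagged_not_called(locus, by_id):
    s = by_id["I-13"]
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=12)
    mappings = map_reads(reads, locus)
    cands = find_junctions(mappings)
    assert cands
    with pytest.raises(LowSupportSV):
        resolve_junction(cands[0], locus, mappings, min_support=10_000)


def test_coverage_flat_without_sv(locus, by_id):
    s = by_id["II-23"]
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=13)
    _, mappings = call_structural_variants(reads, locus)
    cov = coverage_profile(mappings, locus.reference.length)
    # exclude one mean read length at each end (coverage ramp)
    ramp = int(12_000 // cov.window)
    interior = cov.depth[ramp:-ramp]
    assert interior.std() / interior.mean() < 0.2


def test_coverage_half_depth_over_het_deletion(locus, by_id):
    s = by_id["I-13"]
    reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=30, rng=14)
    _, mappings = call_structural_variants(reads, locus)
    cov = coverage_profile(mappings, locus.reference.length)
    flank = (cov.mean_over(5_000, 20_000) + cov.mean_over(50_000, 70_000)) / 2
    inside = cov.mean_over(27_000, 43_000)
    assert 0.35 <= inside / flank <= 0.65


def test_zero_false_positives_across_sv_free_type_ii(locus, cohort):
    """No junction call on any SV-free type II sample's simulation."""
    sv_free = [s for s in cohort if s.group == "II" and not s.is_sv_carrier]
    assert len(sv_free) == 28
    for i, s in enumerate(sv_free):
        reads = simulate_wgs_reads(s.hap1_seq, s.hap2_seq, depth=25,
                                   rng=2_000 + i, sample_id=s.sample_id)
        calls, _ = call_structural_variants(reads, locus)
        assert calls == [], s.sample_id
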