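"""Alignment, amplicon assignment, het-site detection, clustering, consensus."""

from collections import Counter

import numpy as np
import pytest

from haplotile.align import align_read, align_reads, assign_amplicon
from haplotile.cluster import (
    InsufficientCoverageError,
    build_pileup,
    call_consensus,
    cluster_alleles,
    detect_het_sites,
)
from haplotile.cohort import build_sample
from haplotile.pcr import simulate_amplicon
from haplotile.simulate import ErrorModel, simulate_reads

ERROR_FREE = ErrorModel(0, 0, 0, 6_000, 1_000)


def _amp_reads(locus, sample, amp_index, depth, model, rng, hap="both"):
    amp = locus.panel.amplicons[amp_index]
    reads = []
    for h in ("H1", "H2"):
        if hap != "both" and h != hap:
            continue
        product = simulate_amplicon(sample.hap_seq(h), amp.pair, locus.lr_max_product)
        reads.extend(
            simulate_reads(product, depth=depth, error_model=model, rng=rng,
                           sample_id=sample.sample_id, haplotype=h,
                           amplicon=amp.name)
        )
    return reads


def test_alignment_and_assignment(locus, by_id):
    s = by_id["II-23"]
    rng = np.random.default_rng(1)
    reads = _amp_reads(locus, s, 3, depth=3, model=ERROR_FREE, rng=rng)
    alns = align_reads(reads, locus.reference.sequence)
    assert len(alns) == len(reads)
    for a in alns:
        assert a.identity > 0.99
        assert assign_amplicon(a, locus.panel) == "amplicon4"


def test_overlap_zone_assignment_by_majority_fraction(locus):
    # a read living 70% inside amplicon 1's exclusive zone
    a1 = locus.panel.amplicons[0]
    start = a1.end - 5_000  # read: 5 kb inside amplicon 1, 1 kb beyond its end
    frag = locus.reference.sequence[start : start + 6_000]
    aln = align_read(frag, locus.reference.sequence)
    assert assign_amplicon(aln, locus.panel) == "amplicon1"


def test_unalignable_read_returns_none(locus):
    rng = np.random.default_rng(0)
    junk = "".join(rng.choice(list("ACGT"), 2_000))
    assert align_read(junk, locus.reference.sequence) is None


def test_homozygous_amplicon_has_no_het_sites(locus, by_id):
    s = by_id["II-23"]  # both haplotypes identical to the reference
    rng = np.random.default_rng(2)
    reads = _amp_reads(locus, s, 0, depth=15, model=ERROR_FREE, rng=rng)
    alns = align_reads(reads, locus.reference.sequence)
    pile = build_pileup(alns, locus.panel.amplicons[0].interval,
                        locus.reference.sequence)
    assert detect_het_sites(pile) == []
    clusters = cluster_alleles(pile, [], "amplicon1")
    assert len(clusters) == 1 and clusters[0].n_reads == len(alns)


def test_het_snv_detected_under_noise(locus, marked_by_id):
    """A 50/50 SNV at depth ~60 clears the floor; 2% noise does not."""
    s = marked_by_id["II-23"]  # marker SNVs on haplotype 2 only
    rng = np.random.default_rng(3)
    model = ErrorModel(0.02, 0.0, 0.0, 8_000, 2_000)
    reads = _amp_reads(locus, s, 0, depth=30, model=model, rng=rng)
    alns = align_reads(reads, locus.reference.sequence)
    pile = build_pileup(alns, locus.panel.amplicons[0].interval,
                        locus.reference.sequence)
    sites = detect_het_sites(pile)
    positions = {x.pos for x in sites}
    # every planted marker inside amplicon 1 is found, and nothing else
    from haplotile.simulate import PHASING_SNV_POSITIONS

    expected = {
        p for p in PHASING_SNV_POSITIONS
        if locus.panel.amplicons[0].start + 500 <= p <= locus.panel.amplicons[0].end - 500
    }
    assert expected <= positions
    assert positions <= expected  # no noise site at 2% substitution error


def test_insufficient_coverage_raises(locus, by_id):
    s = by_id["II-23"]
    rng = np.random.default_rng(4)
    reads = _amp_reads(locus, s, 0, depth=2, model=ERROR_FREE, rng=rng, hap="H1")
    alns = align_reads(reads, locus.reference.sequence)
    pile = build_pileup(alns, locus.panel.amplicons[0].interval,
                        locus.reference.sequence)
    with pytest.raises(InsufficientCoverageError):
        detect_het_sites(pile, min_depth=20)


def test_cluster_purity_against_truth_labels(locus, marked_by_id):
    """Two clusters, >= 99% truth-label purity at the default error model."""
    from haplotile.simulate import AMPLICON_ERROR_MODEL

    s = marked_by_id["II-23"]
    rng = np.random.default_rng(6)
    reads = _amp_reads(locus, s, 1, depth=30, model=AMPLICON_ERROR_MODEL, rng=rng)
    alns = align_reads(reads, locus.reference.sequence)
    pile = build_pileup(alns, locus.panel.amplicons[1].interval,
                        locus.reference.sequence)
    clusters = cluster_alleles(pile, detect_het_sites(pile), "amplicon2")
    assert len(clusters) == 2
    n_correct = n_total = 0
    for c in clusters:
        labels = Counter(pile.alignments[i].meta.haplotype for i in c.member_indices)
        n_correct += labels.most_common(1)[0][1]
        n_total += c.n_reads
    assert n_correct / n_total >= 0.99


def test_consensus_exact_on_error_free_reads(locus, by_id):
    s = by_id["I-07"]  # c.380C>T on haplotype 1
    rng = np.random.default_rng(7)
    reads = _amp_reads(locus, s, 3, depth=15, model=ERROR_FREE, rng=rng, hap="H1")
    alns = align_reads(reads, locus.reference.sequence)
    amp = locus.panel.amplicons[3]
    pile = build_pileup(alns, amp.interval, locus.reference.sequence)
    clusters = cluster_alleles(pile, [], amp.name)
    cons = call_consensus(pile, clusters[0], locus.reference.sequence)
    assert cons.sequence == s.hap1_seq[amp.start - 1 : amp.end]


def test_low_support_flags(locus, by_id):
    s = by_id["II-23"]
    rng = np.random.default_rng(8)
    reads = _amp_reads(locus, s, 0, depth=2, model=ERROR_FREE, rng=rng, hap="H1")
    alns = align_reads(reads, locus.reference.sequence)
    pile = build_pileup(alns, locus.panel.amplicons[0].interval,
                        locus.reference.sequence)
    clusters = cluster_alleles(pile, [], "amplicon1", min_reads=10)
    assert clusters[0].low_support
    cons = call_consensus(pile, clusters[0], locus.reference.sequence)
    assert cons.low_support
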