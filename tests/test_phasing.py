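"""Overlap phasing: junction chaining vs the exhaustive oracle, dropout scan."""

import numpy as np
import pytest

from haplotile.phasing import (
    DROPOUT,
    ContaminationError,
    PhasedChain,
    JunctionEvidence,
    brute_force_phase,
    detect_dropout_pattern,
    phase_amplicons,
)


class DictAlleles:
    """Minimal allele carrier for synthetic phasing instances."""

    def __init__(self, alleles: dict[int, str]):
        self.alleles = alleles

    def base_at(self, pos):
        return self.alleles.get(pos)


def _instance(rng, k_amplicons=4, sites_per_overlap=3):
    """Random small instance: two latent haplotypes over shared overlap sites."""
    overlaps = []
    cluster_sets = []
    site_sets = []
    for j in range(k_amplicons - 1):
        lo = j * 1_000 + 1
        positions = sorted(
            rng.choice(np.arange(lo, lo + 100), size=sites_per_overlap, replace=False)
        )
        overlaps.append((lo, lo + 99))
        site_sets.append([int(p) for p in positions])
    # latent haplotype alleles per site
    hap_alleles = {}
    for sites in site_sets:
        for p in sites:
            a, b = rng.choice(list("ACGT"), size=2, replace=False)
            het = rng.random() < 0.8
            hap_alleles[p] = (a, b if het else a)
    for i in range(k_amplicons):
        visible = []
        if i > 0:
            visible += site_sets[i - 1]
        if i < k_amplicons - 1:
            visible += site_sets[i]
        n_clusters = int(rng.integers(1, 3))
        if n_clusters == 1:
            cluster_sets.append(
                [DictAlleles({p: hap_alleles[p][0] for p in visible})]
            )
        else:
            cluster_sets.append(
                [
                    DictAlleles({p: hap_alleles[p][h] for p in visible})
                    for h in (0, 1)
                ]
            )
    return cluster_sets, overlaps


def test_agrees_with_exhaustive_oracle_on_fuzzed_instances():
    """At every unambiguous junction the greedy chaining equals the
    2^(k-1)-enumeration optimum, over 200 random instances."""
    rng = np.random.default_rng(20_240_001)
    for trial in range(200):
        k = int(rng.integers(2, 5))
        cluster_sets, overlaps = _instance(rng, k_amplicons=k)
        chain = phase_amplicons(cluster_sets, overlaps)
        best, _score = brute_force_phase(cluster_sets, overlaps)
        for j, ev in enumerate(chain.junctions):
            if ev.ambiguous:
                continue
            got = (chain.provenance[0][j], chain.provenance[0][j + 1],
                   chain.provenance[1][j], chain.provenance[1][j + 1])
            want = (best[0][j], best[0][j + 1], best[1][j], best[1][j + 1])
            swapped = (want[2], want[3], want[0], want[1])
            assert got in (want, swapped), f"trial {trial} junction {j}"


def test_majority_pairing_on_conflicting_evidence():
    """3 sites vote parallel, 1 votes crossed: majority wins, 2 amplicons."""
    up = [DictAlleles({1: "A", 2: "A", 3: "A", 4: "A"}),
          DictAlleles({1: "C", 2: "C", 3: "C", 4: "C"})]
    dn = [DictAlleles({1: "A", 2: "A", 3: "A", 4: "C"}),
          DictAlleles({1: "C", 2: "C", 3: "C", 4: "A"})]
    chain = phase_amplicons([up, dn], [(1, 4)])
    assert not chain.junctions[0].ambiguous
    assert chain.provenance[0] == [0, 0] and chain.provenance[1] == [1, 1]
    best, _ = brute_force_phase([up, dn], [(1, 4)])
    assert best[0] == [0, 0]


def test_single_amplicon_identity():
    clusters = [[DictAlleles({1: "A"}), DictAlleles({1: "C"})]]
    best, _ = brute_force_phase(clusters, [])
    assert best == [[0], [1]]
    chain = phase_amplicons(clusters, [])
    assert chain.provenance == [[0], [1]]


def test_single_informative_site_decides_pairing():
    up = [DictAlleles({5: "G"}), DictAlleles({5: "T"})]
    dn = [DictAlleles({5: "T"}), DictAlleles({5: "G"})]
    chain = phase_amplicons([up, dn], [(5, 5)])
    assert not chain.junctions[0].ambiguous
    assert chain.provenance[0] == [0, 1]  # crossed pairing followed the SNV


def test_homozygous_panel_all_ambiguous():
    clusters = [[DictAlleles({})] for _ in range(4)]
    chain = phase_amplicons(clusters, [(1, 10), (11, 20), (21, 30)])
    assert chain.provenance[0] == chain.provenance[1] == [0, 0, 0, 0]
    assert all(j.ambiguous for j in chain.junctions)


def test_contamination_error_on_three_clusters():
    three = [DictAlleles({}), DictAlleles({}), DictAlleles({})]
    with pytest.raises(ContaminationError):
        phase_amplicons([three], [])


def _chain(prov0, prov1):
    return PhasedChain(
        provenance=[list(prov0), list(prov1)],
        junctions=[JunctionEvidence(j, (), 0, 0, False) for j in range(3)],
    )


def test_dropout_pattern_rules():
    sv = detect_dropout_pattern(_chain([0, DROPOUT, DROPOUT, 0], [0, 0, 0, 1]))
    assert sv.kind == "sv_candidate"
    assert sv.amplicons == (1, 2)  # amplicons 2 and 3 (0-based)
    none = detect_dropout_pattern(_chain([0, 0, 0, 0], [1, 1, 1, 1]))
    assert none.kind == "none"
    fail = detect_dropout_pattern(_chain([DROPOUT, 0, 0, 0], [DROPOUT, 0, 0, 0]))
    assert fail.kind == "assay_failure" and fail.amplicons == (0,)
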