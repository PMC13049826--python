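"""End-to-end per-sample reconstruction: simulate -> align -> cluster ->
phase -> call.

This is the orchestration layer the CLI and the analysis drivers share.
Per amplicon, reads are aligned and clustered into alleles; an amplicon
yielding a single cluster at roughly half the read mass of the two-cluster
amplicons is marked single-allele (one haplotype failed to amplify); the
overlap phaser then chains clusters into two haplotypes, the dropout scan
flags the deletion signature, and each haplotype's merged consensus is
diffed against the reference for reportable variant calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import align_reads, assign_amplicon
from .calling import VariantCall, annotate, diff_haplotype, filter_reportable
from .cluster import (
    AlleleCluster,
    Consensus,
    build_pileup,
    call_consensus,
    cluster_alleles,
    detect_het_sites,
    refine_indel_calls,
    InsufficientCoverageError,
)
from .cohort import DiploidSample
from .variants import Variant, normalize_variant
from .pcr import Dropout, simulate_amplicon
from .phasing import DROPOUT, DropoutFlag, PhasedChain, detect_dropout_pattern, phase_amplicons
from .simulate import (
    AMPLICON_ERROR_MODEL,
    ErrorModel,
    LocusModel,
    SimulatedRead,
    simulate_reads,
)

__all__ = [
    "AmpliconCallSet",
    "SampleReconstruction",
    "simulate_sample_amplicon_reads",
    "reconstruct_sample",
    "truth_reportable_names",
]


@dataclass
class AmpliconCallSet:
    """Clusters + consensuses of one amplicon."""

    amplicon_id: str
    clusters: list[AlleleCluster]
    consensuses: list[Consensus]
    n_reads: int
    normalized_mass: float  # aligned bases / amplicon length


@dataclass
class SampleReconstruction:
    sample_id: str
    amplicons: dict[str, AmpliconCallSet]
    chain: PhasedChain
    dropout: DropoutFlag
    hap_calls: list[list[VariantCall]]          # per haplotype, reportable
    hap_all_calls: list[list[VariantCall]]      # per haplotype, unfiltered
    provenance: list[list[int | str]]

    def reportable_names(self, hap: int) -> tuple[str, ...]:
        return tuple(sorted(c.hgvs_c for c in self.hap_calls[hap]))


def simulate_sample_amplicon_reads(
    sample: DiploidSample,
    locus: LocusModel,
    depth: float = 30,
    error_model: ErrorModel = AMPLICON_ERROR_MODEL,
    rng: np.random.Generator | int | None = 0,
) -> list[SimulatedRead]:
    """Amplify all four amplicons from both haplotypes and simulate reads.

    Per-haplotype per-amplicon depth is `depth`; dropout alleles contribute
    no reads, which is the signature later recovered by the pipeline.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    reads: list[SimulatedRead] = []
    for hap in ("H1", "H2"):
        seq = sample.hap_seq(hap)
        for amp in locus.panel:
            product = simulate_amplicon(seq, amp.pair, locus.lr_max_product)
            if isinstance(product, Dropout):
                continue
            reads.extend(
                simulate_reads(
                    product,
                    depth=depth,
                    error_model=error_model,
                    rng=rng,
                    sample_id=sample.sample_id,
                    haplotype=hap,
                    amplicon=amp.name,
                )
            )
    return reads


def reconstruct_sample(
    reads: list[SimulatedRead],
    locus: LocusModel,
    sample_id: str = "sample",
    min_depth: int = 20,
    min_reads: int = 10,
    dropout_mass_ratio: float = 0.7,
) -> SampleReconstruction:
    """Full reconstruction of one sample from amplicon reads."""
    ref = locus.reference.sequence
    alignments = align_reads(reads, ref)
    by_amp: dict[str, list] = {a.name: [] for a in locus.panel}
    for aln in alignments:
        amp = assign_amplicon(aln, locus.panel)
        if amp is not None:
            by_amp[amp].append(aln)

    call_sets: dict[str, AmpliconCallSet] = {}
    pileups: dict[str, object] = {}
    for amp in locus.panel:
        alns = by_amp[amp.name]
        if not alns:
            call_sets[amp.name] = AmpliconCallSet(amp.name, [], [], 0, 0.0)
            continue
        pile = build_pileup(alns, amp.interval, ref)
        pileups[amp.name] = pile
        try:
            sites = detect_het_sites(pile, min_depth=min_depth)
        except InsufficientCoverageError:
            sites = []
        clusters = cluster_alleles(pile, sites, amp.name, min_reads=min_reads)
        consensuses = [call_consensus(pile, c, ref) for c in clusters]
        mass = sum(a.aligned_span for a in alns) / amp.length
        call_sets[amp.name] = AmpliconCallSet(
            amp.name, clusters, consensuses, len(alns), mass
        )

    # single-allele detection: an amplicon carrying roughly half the read
    # mass of its peers lost one allele (the other failed to amplify); a
    # mass-deficient amplicon that still split into two "clusters" did so
    # on alignment noise, so its reads are re-merged into one allele group
    masses = [call_sets[a.name].normalized_mass for a in locus.panel]
    # reference mass: mean of the two deepest amplicons (both alleles
    # amplified there), so a single-allele amplicon sits near ratio 0.5,
    # well clear of the detection threshold
    ref_mass = float(np.mean(sorted(masses)[-2:]))
    single_allele = []
    for amp in locus.panel:
        cs = call_sets[amp.name]
        flag = (
            ref_mass > 0
            and cs.n_reads > 0
            and cs.normalized_mass < dropout_mass_ratio * ref_mass
        )
        if flag and len(cs.clusters) == 2:
            merged = AlleleCluster(
                amp.name,
                0,
                sorted(cs.clusters[0].member_indices + cs.clusters[1].member_indices),
                cs.clusters[0].read_ids + cs.clusters[1].read_ids,
                {},
                low_support=cs.n_reads < min_reads,
            )
            cs.clusters = [merged]
            cs.consensuses = [call_consensus(pileups[amp.name], merged, ref)]
        single_allele.append(bool(flag))

    cluster_sets = [call_sets[a.name].consensuses for a in locus.panel]
    overlaps = [locus.panel.overlap_interval(j) for j in range(len(locus.panel) - 1)]
    chain = phase_amplicons(cluster_sets, overlaps, single_allele=single_allele,
                            probe_step=1)
    dropout = detect_dropout_pattern(chain)

    # each amplicon is responsible for calling up to the midpoint of its
    # overlaps, where its coverage is deepest; this prevents double (and
    # edge-thinned) calls in shared regions
    amps = list(locus.panel)
    responsibility: list[tuple[int, int]] = []
    for i, amp in enumerate(amps):
        lo = amp.start if i == 0 else (amps[i].start + amps[i - 1].end) // 2 + 1
        hi = amp.end if i == len(amps) - 1 else (amps[i + 1].start + amps[i].end) // 2
        responsibility.append((lo, hi))

    hap_calls: list[list[VariantCall]] = []
    hap_all: list[list[VariantCall]] = []
    for h in (0, 1):
        calls: list[VariantCall] = []
        seen = set()
        for i, amp in enumerate(amps):
            prov = chain.provenance[h][i]
            if prov == DROPOUT:
                continue
            cons = call_sets[amp.name].consensuses[prov]
            variants = diff_haplotype(cons.sequence, locus.reference,
                                      region=amp.interval)
            pile = pileups.get(amp.name)
            if pile is not None:
                cluster = call_sets[amp.name].clusters[prov]
                tuples = [(v.pos, v.ref, v.alt) for v in variants]
                # harvest recurrent indel events straight from member reads:
                # a true indel near the detection floor can miss the column
                # consensus yet still dominate the hypothesis vote below
                harvest: dict = {}
                for row in cluster.member_indices:
                    for e in pile.events[row] or ():
                        if len(e[1]) == 1 and len(e[2]) == 1:
                            continue
                        harvest[e] = harvest.get(e, 0) + 1
                extra = [
                    e
                    for e, n_e in sorted(
                        harvest.items(), key=lambda kv: (-kv[1], repr(kv[0]))
                    )
                    if n_e >= 4
                ][:25]
                for e in extra:
                    if e not in tuples:
                        tuples.append(e)
                tuples = refine_indel_calls(tuples, pile, cluster, ref)
                variants = []
                for pos, vr, va in tuples:
                    try:
                        variants.append(
                            normalize_variant(Variant(pos, vr, va), locus.reference)
                        )
                    except Exception:
                        continue
            lo, hi = responsibility[i]
            for v in variants:
                if not (lo <= v.pos <= hi) or v in seen:
                    continue
                seen.add(v)
                calls.append(annotate(v, locus, haplotype=f"H{h + 1}"))
        calls.sort(key=lambda c: c.variant.pos)
        hap_all.append(calls)
        hap_calls.append(filter_reportable(calls))

    return SampleReconstruction(
        sample_id=sample_id,
        amplicons=call_sets,
        chain=chain,
        dropout=dropout,
        hap_calls=hap_calls,
        hap_all_calls=hap_all,
        provenance=chain.provenance,
    )


def truth_reportable_names(sample: DiploidSample, hap: str) -> tuple[str, ...]:
    """The encoded (canonical) reportable truth for one haplotype."""
    return tuple(sorted(sample.truth_variant_names(hap)))
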