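"""Chaining per-amplicon allele clusters into two full-length haplotypes.

Adjacent amplicons share >= 3 kb of sequence; heterozygous variants inside
an overlap that are seen by both amplicons' cluster pairs decide which
upstream allele continues into which downstream allele.  A junction's
pairing is accepted only when one orientation strictly dominates the other;
otherwise an arbitrary pairing is used and the junction is flagged
ambiguous (a homozygous overlap simply cannot be phased by this design).

An amplicon that amplified only one of the two alleles (detected upstream
by read-depth evidence) contributes its single cluster to the haplotype
whose overlap alleles it matches; the other haplotype records DROPOUT
there.  A haplotype showing DROPOUT for a contiguous internal run of
amplicons while the other haplotype covers the whole panel is the
diagnostic signature of a large deletion removing primer sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct
from typing import Protocol, Sequence

__all__ = [
    "AlleleCarrier",
    "JunctionEvidence",
    "PhasedChain",
    "DROPOUT",
    "phase_amplicons",
    "brute_force_phase",
    "detect_dropout_pattern",
    "DropoutFlag",
    "ContaminationError",
]

DROPOUT = "DROPOUT"


class ContaminationError(ValueError):
    """More than two allele clusters in a single amplicon."""


class AlleleCarrier(Protocol):
    """Anything exposing per-position allele keys (a consensus, or test stub)."""

    def base_at(self, pos: int) -> str | None: ...


@dataclass(frozen=True)
class JunctionEvidence:
    """Scoring record for one junction between adjacent amplicons."""

    junction: int                      # 0-based: between amplicon j and j+1
    informative_sites: tuple[int, ...] # overlap positions that discriminated
    score_parallel: int                # up0-down0 / up1-down1 agreement
    score_crossed: int                 # up0-down1 / up1-down0 agreement
    ambiguous: bool


@dataclass
class PhasedChain:
    """Cluster-of-origin per amplicon for both haplotypes, plus flags."""

    provenance: list[list[int | str]]  # [hap][amplicon] -> cluster index | DROPOUT
    junctions: list[JunctionEvidence]

    def haplotype_provenance(self, hap: int) -> list[int | str]:
        return self.provenance[hap]


def phase_amplicons(
    cluster_sets: Sequence[Sequence[AlleleCarrier]],
    overlap_intervals: Sequence[tuple[int, int]],
    single_allele: Sequence[bool] | None = None,
    probe_step: int = 1,
) -> PhasedChain:
    """Chain per-amplicon clusters into two haplotypes.

    Parameters
    ----------
    cluster_sets:
        Per amplicon: 0 (total dropout), 1 or 2 allele carriers.
    overlap_intervals:
        1-based inclusive locus interval shared by amplicons j and j+1.
    single_allele:
        Per amplicon: True when depth evidence says only one allele
        amplified; its single carrier then serves one haplotype and the
        other records DROPOUT.
    probe_step:
        Stride over the overlap when probing for discriminating positions.
    """
    k = len(cluster_sets)
    if single_allele is None:
        single_allele = [False] * k
    for cs in cluster_sets:
        if len(cs) > 2:
            raise ContaminationError(f"{len(cs)} clusters in one amplicon")
    if len(overlap_intervals) != k - 1:
        raise ValueError("need one overlap interval per junction")

    provenance: list[list[int | str]] = [[], []]
    junctions: list[JunctionEvidence] = []

    def carrier_of(amp: int, hap: int) -> AlleleCarrier | None:
        idx = provenance[hap][amp]
        if idx == DROPOUT:
            return None
        return cluster_sets[amp][idx]

    # initialise with the first amplicon
    first = cluster_sets[0]
    if len(first) == 0:
        provenance[0].append(DROPOUT)
        provenance[1].append(DROPOUT)
    elif len(first) == 1:
        provenance[0].append(0)
        provenance[1].append(DROPOUT if single_allele[0] else 0)
    else:
        provenance[0].append(0)
        provenance[1].append(1)

    for j in range(k - 1):
        nxt = cluster_sets[j + 1]
        lo, hi = overlap_intervals[j]
        positions = list(range(lo, hi + 1, probe_step))
        up = [carrier_of(j, 0), carrier_of(j, 1)]

        if len(nxt) == 0:
            provenance[0].append(DROPOUT)
            provenance[1].append(DROPOUT)
            junctions.append(JunctionEvidence(j, (), 0, 0, True))
            continue

        if len(nxt) == 2:
            # score the two pairings over discriminating overlap positions
            sites, par, cro = [], 0, 0
            for p in positions:
                kn = [nxt[0].base_at(p), nxt[1].base_at(p)]
                ku = [c.base_at(p) if c is not None else None for c in up]
                if None in kn:
                    continue
                informative = len(set(kn)) > 1 or (
                    ku[0] is not None and ku[1] is not None and ku[0] != ku[1]
                )
                if not informative:
                    continue
                s_par = sum(1 for h in (0, 1) if ku[h] is not None and ku[h] == kn[h])
                s_cro = sum(1 for h in (0, 1) if ku[h] is not None and ku[h] == kn[1 - h])
                if s_par != s_cro:
                    sites.append(p)
                par += s_par
                cro += s_cro
            ambiguous = par == cro
            if cro > par:
                order = (1, 0)
            else:
                order = (0, 1)
            provenance[0].append(order[0])
            provenance[1].append(order[1])
            junctions.append(JunctionEvidence(j, tuple(sites), par, cro, ambiguous))
            continue

        # single cluster downstream
        if not single_allele[j + 1]:
            # both haplotypes share the one cluster (homozygous amplicon)
            provenance[0].append(0)
            provenance[1].append(0)
            junctions.append(JunctionEvidence(j, (), 0, 0, True))
            continue

        # one allele amplified: decide which haplotype it extends
        if up[0] is None or up[1] is None:
            # only one haplotype is live upstream: the surviving chain
            # continues through the gap (flanking-consistency rule)
            keeper = 0 if up[0] is not None else 1
            if up[keeper] is None:  # both dropped upstream: arbitrary
                keeper = 0
            provenance[keeper].append(0)
            provenance[1 - keeper].append(DROPOUT)
            junctions.append(JunctionEvidence(j, (), 0, 0, up[keeper] is None))
            continue
        scores = [0, 0]
        sites = []
        for p in positions:
            kn = nxt[0].base_at(p)
            if kn is None:
                continue
            ku = [c.base_at(p) if c is not None else None for c in up]
            if ku[0] is None or ku[1] is None or ku[0] == ku[1]:
                continue
            sites.append(p)
            for h in (0, 1):
                if ku[h] == kn:
                    scores[h] += 1
        ambiguous = scores[0] == scores[1]
        keeper = 0 if scores[0] >= scores[1] else 1
        provenance[keeper].append(0)
        provenance[1 - keeper].append(DROPOUT)
        junctions.append(
            JunctionEvidence(j, tuple(sites), scores[0], scores[1], ambiguous)
        )

    return PhasedChain(provenance=provenance, junctions=junctions)


def brute_force_phase(
    cluster_sets: Sequence[Sequence[AlleleCarrier]],
    overlap_intervals: Sequence[tuple[int, int]],
    probe_step: int = 1,
) -> tuple[list[list[int]], int]:
    """Exhaustive chaining oracle for small panels (<= 6 amplicons).

    Enumerates every per-amplicon cluster orientation, scores total overlap
    agreement along both haplotypes, and returns (best provenance, score).
    Amplicons must have 1 or 2 clusters (no dropout handling); used in tests
    as the ground truth against :func:`phase_amplicons`.
    """
    k = len(cluster_sets)
    if k > 6:
        raise ValueError("oracle is exponential; use <= 6 amplicons")
    choices = []
    for cs in cluster_sets:
        if len(cs) == 1:
            choices.append([(0, 0)])
        elif len(cs) == 2:
            choices.append([(0, 1), (1, 0)])
        else:
            raise ValueError("oracle needs 1 or 2 clusters per amplicon")
    # fix the first amplicon's orientation: haplotype labels are arbitrary
    if len(choices[0]) == 2:
        choices[0] = [(0, 1)]

    best_score, best = -1, None
    for combo in iproduct(*choices):
        score = 0
        for j in range(k - 1):
            lo, hi = overlap_intervals[j]
            up = [cluster_sets[j][combo[j][h]] for h in (0, 1)]
            dn = [cluster_sets[j + 1][combo[j + 1][h]] for h in (0, 1)]
            for p in range(lo, hi + 1, probe_step):
                ku = [c.base_at(p) for c in up]
                kn = [c.base_at(p) for c in dn]
                if None in ku or None in kn:
                    continue
                if len(set(ku)) == 1 and len(set(kn)) == 1:
                    continue
                score += sum(1 for h in (0, 1) if ku[h] == kn[h])
        if score > best_score:
            best_score = score
            best = [list(c) for c in zip(*combo)]
    return best, best_score


@dataclass(frozen=True)
class DropoutFlag:
    """Result of the amplicon-dropout scan over a phased chain."""

    kind: str                      # "sv_candidate" | "assay_failure" | "none"
    haplotype: int | None          # index of the affected haplotype
    amplicons: tuple[int, ...]     # 0-based indices of dropped amplicons


def detect_dropout_pattern(chain: PhasedChain) -> DropoutFlag:
    """Flag the deletion signature: one haplotype drops a contiguous internal
    run of amplicons while the other covers the whole panel."""
    k = len(chain.provenance[0])
    dropped = [
        [i for i in range(k) if chain.provenance[h][i] == DROPOUT] for h in (0, 1)
    ]
    both = set(dropped[0]) & set(dropped[1])
    if both:
        return DropoutFlag(kind="assay_failure", haplotype=None,
                           amplicons=tuple(sorted(both)))
    for h in (0, 1):
        d = dropped[h]
        if not d or dropped[1 - h]:
            continue
        contiguous = d == list(range(d[0], d[-1] + 1))
        internal = d[0] > 0 and d[-1] < k - 1
        if contiguous and internal:
            return DropoutFlag(kind="sv_candidate", haplotype=h, amplicons=tuple(d))
    return DropoutFlag(kind="none", haplotype=None, amplicons=())
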