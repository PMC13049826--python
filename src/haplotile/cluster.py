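"""Heterozygous-site detection, two-allele read clustering and consensus.

Reads of one amplicon come from at most two alleles of a diploid sample.
Per-column pileups over the amplicon interval expose heterozygous sites
(two alleles above a minor-allele fraction/count floor); each read's allele
vector over those sites is clustered into at most two groups (site
polarities anchored by transitive adjacent-site linkage, one refinement
pass, deterministic given input order); each group's consensus is the
per-column plurality with ties broken
toward the reference base, so sequencing noise biases toward no-call rather
than a false variant.

Small indels (< 5 bp) are collapsed with the reference key for *site
detection* only — mirroring the noise floor of long-read pileups — but are
retained in the pileup for consensus, so true short indels still reach the
consensus if their reads dominate a cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .align import ReadAlignment

__all__ = [
    "PileupMatrix",
    "HetSite",
    "AlleleCluster",
    "Consensus",
    "build_pileup",
    "detect_het_sites",
    "cluster_alleles",
    "call_consensus",
    "InsufficientCoverageError",
]

# pileup codes: 0..3 = A/C/G/T, 4 = deletion, -1 = not covered
_CODE = {b: i for i, b in enumerate("ACGT")}
_DEL = 4
_BASES = "ACGT-"
_LUT = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def _codes_of(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode("ascii"), np.uint8)]


class InsufficientCoverageError(ValueError):
    pass


@dataclass
class PileupMatrix:
    """Per-read base codes over a reference interval, plus insertion records."""

    region_start: int                     # 1-based
    codes: np.ndarray                     # (n_reads, region_len) int8, true indels
    site_codes: np.ndarray                # same, small indels collapsed to ref
    insertions: list[dict[int, str]]      # per read: ref pos (1-based) -> inserted seq
    alignments: list[ReadAlignment]
    events: list[list[tuple[int, str, str]]] | None = None  # per read, normalized

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]


@dataclass(frozen=True)
class HetSite:
    """A position with two alleles above the detection floor."""

    pos: int          # 1-based locus position
    allele_a: int     # pileup code of the major allele
    allele_b: int     # pileup code of the minor allele
    count_a: int
    count_b: int

    @property
    def alleles(self) -> tuple[str, str]:
        return (_BASES[self.allele_a], _BASES[self.allele_b])


@dataclass
class AlleleCluster:
    """Reads assigned to one allele of one amplicon."""

    amplicon_id: str
    cluster_id: int
    member_indices: list[int]             # rows in the pileup
    read_ids: list[str]
    signature: dict[int, int]             # het-site pos -> allele code
    low_support: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.member_indices)


@dataclass
class Consensus:
    """Reference-guided consensus of one allele cluster."""

    amplicon_id: str
    cluster_id: int
    sequence: str
    ref_start: int                        # 1-based first reference column
    ref_positions: np.ndarray             # per consensus base: ref pos (ins: anchor)
    support: np.ndarray                   # per consensus base: agreeing fraction
    n_reads: int
    low_support: bool = False

    def base_at(self, pos: int) -> str | None:
        """Consensus base at a reference position ('-' if deleted, None if absent)."""
        i = np.searchsorted(self.ref_positions, pos)
        if i < len(self.ref_positions) and self.ref_positions[i] == pos:
            return self.sequence[i]
        lo, hi = self.ref_positions[0], self.ref_positions[-1]
        if lo <= pos <= hi:
            return "-"
        return None


def _trim(r: str, a: str) -> tuple[str, str]:
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
    return r, a


def _consolidate(
    events: list[list], reference: str, max_gap: int = 8
) -> list[list]:
    """Merge runs of events that are one indel in disguise.

    Optimal alignments of an indel through repeat sequence are degenerate:
    the same 12-bp deletion may surface as del+SNV+del across reads.  A run
    of events (separated by <= ``max_gap`` matched bases) whose merged
    ref/alt trims to a pure insertion or deletion is exactly such an
    equivalent decomposition and is replaced by the merged event; anything
    else is left alone so genuine neighbouring variants keep their columns.
    """
    out: list[list] = []
    i = 0
    while i < len(events):
        pos, r, a, endc = events[i]
        acc_pos, acc_r, acc_a, acc_end = pos, r, a, endc
        best_pure = best_balanced = None
        j = i + 1
        while j < len(events):
            npos, nr, na, nend = events[j]
            gap = (npos if nr else npos + 1) - acc_end - 1
            if gap < 0 or gap > max_gap:
                break
            fill = reference[acc_end : acc_end + gap]
            if acc_r == "" and (fill or nr):
                acc_pos = acc_end + 1
            acc_r += fill + nr
            acc_a += fill + na
            acc_end = nend
            t_r, t_a = _trim(acc_r, acc_a)
            if t_r == "" or t_a == "":
                best_pure = (j, [acc_pos, acc_r, acc_a, acc_end])
            elif len(t_r) == len(t_a):
                # a substitution-block representation (e.g. ins+del hiding
                # an SNV): painting it elementwise restores the true column
                best_balanced = (j, [acc_pos, acc_r, acc_a, acc_end])
            j += 1
        best = best_pure or best_balanced
        if best is not None:
            out.append(best[1])
            i = best[0] + 1
        else:
            out.append(events[i])
            i += 1
    return out


def _read_events(
    aln: ReadAlignment, reference: str, max_gap: int = 8
) -> list[tuple[int, str, str]]:
    """A read's divergence from the reference as consolidated, 3'-normalized
    (pos, ref, alt) events (1-based)."""
    events: list[list] = []  # [pos, ref, alt, last_ref_consumed]
    rpos = aln.locus_start
    qpos = 0
    q = aln.query
    for length, op in aln.cigar:
        if op in "=M":
            rpos += length
            qpos += length
            continue
        if op == "X":
            r, a = reference[rpos - 1 : rpos - 1 + length], q[qpos : qpos + length]
            pos, endc = rpos, rpos + length - 1
            rpos += length
            qpos += length
        elif op == "D":
            r, a = reference[rpos - 1 : rpos - 1 + length], ""
            pos, endc = rpos, rpos + length - 1
            rpos += length
        else:  # I
            r, a = "", q[qpos : qpos + length]
            pos, endc = rpos - 1, rpos - 1  # anchored after pos
            qpos += length
        if events:
            # directly abutting indel ops (e.g. "1D1I") form one event
            prev = events[-1]
            gap = (pos if r else pos + 1) - prev[3] - 1
            if gap == 0 and (len(prev[1]) != len(prev[2]) or len(r) != len(a)):
                if prev[1] == "" and r:
                    prev[0] = prev[3] + 1
                prev[1] += r
                prev[2] += a
                prev[3] = endc
                continue
        events.append([pos, r, a, endc])

    events = _consolidate(events, reference, max_gap)
    return [_normalize_event(pos, r, a, reference) for pos, r, a, _ in events]


def _normalize_event(pos: int, r: str, a: str, reference: str) -> tuple[int, str, str]:
    """Trim the common affix and 3'-shift a pure indel (string-level)."""
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1
    n = len(reference)
    if a == "" and r:
        while pos + len(r) <= n and reference[pos + len(r) - 1] == r[0]:
            r = r[1:] + reference[pos + len(r) - 1]
            pos += 1
    elif r == "" and a:
        while pos < n and reference[pos] == a[0]:
            a = a[1:] + reference[pos]
            pos += 1
    return pos, r, a


def build_pileup(
    alignments: list[ReadAlignment],
    region: tuple[int, int],
    reference: str,
    min_indel_keep: int = 5,
) -> PileupMatrix:
    """Column-wise pileup over a 1-based inclusive region.

    Each read is painted as "reference where covered" and then overwritten
    by its normalized divergence events, so equivalent alignments of the
    same edit agree column-for-column.  ``site_codes`` additionally
    collapses indels shorter than ``min_indel_keep`` with the reference key
    (the het-site noise floor); ``codes`` keeps them for consensus.
    """
    start, end = region
    n = end - start + 1
    ref_codes = _codes_of(reference[start - 1 : end])
    codes = np.full((len(alignments), n), -1, dtype=np.int8)
    site_codes = np.full((len(alignments), n), -1, dtype=np.int8)
    insertions: list[dict[int, str]] = []
    all_events: list[list[tuple[int, str, str]]] = []
    for row, aln in enumerate(alignments):
        ins: dict[int, str] = {}
        lo = max(aln.locus_start, start)
        hi = min(aln.locus_end, end)
        if lo <= hi:
            codes[row, lo - start : hi - start + 1] = ref_codes[
                lo - start : hi - start + 1
            ]
        read_events = _read_events(aln, reference)
        all_events.append(read_events)
        for pos, r, a in read_events:
            if r == "":  # insertion after `pos`
                if start <= pos <= end and a:
                    ins[pos] = a
                continue
            e_lo = max(pos, start)
            e_hi = min(pos + len(r) - 1, end)
            if e_lo > e_hi:
                continue
            net = abs(len(r) - len(a))
            for p in range(e_lo, e_hi + 1):
                i = p - pos  # offset within the event
                if i < len(a):
                    codes[row, p - start] = _CODE.get(a[i], -1)
                    site_codes[row, p - start] = codes[row, p - start]
                else:
                    codes[row, p - start] = _DEL
                    site_codes[row, p - start] = (
                        ref_codes[p - start] if net < min_indel_keep else _DEL
                    )
            if len(a) > len(r):
                anchor = pos + len(r) - 1
                if start <= anchor <= end:
                    ins[anchor] = a[len(r) :]
        insertions.append(ins)
    # mirror matched (reference) columns into the site-detection matrix
    matched = (site_codes == -1) & (codes >= 0)
    site_codes[matched] = codes[matched]
    return PileupMatrix(
        region_start=start,
        codes=codes,
        site_codes=site_codes,
        insertions=insertions,
        alignments=list(alignments),
        events=all_events,
    )


def detect_het_sites(
    pileup: PileupMatrix,
    min_depth: int = 20,
    min_fraction: float = 0.20,
    min_count: int = 5,
) -> list[HetSite]:
    """Columns where two alleles both clear the minor-allele floor.

    Raises :class:`InsufficientCoverageError` when the pileup has fewer
    reads than ``min_depth``.  Homozygous amplicons yield an empty list.
    """
    if pileup.n_reads < min_depth:
        raise InsufficientCoverageError(
            f"{pileup.n_reads} reads < min_depth {min_depth}"
        )
    m = pileup.site_codes
    sites: list[HetSite] = []
    counts = np.zeros((5, m.shape[1]), dtype=np.int32)
    for code in range(5):
        counts[code] = (m == code).sum(axis=0)
    depth = counts.sum(axis=0)
    order = np.argsort(-counts, axis=0, kind="stable")
    top, second = order[0], order[1]
    cn = counts[top, np.arange(m.shape[1])]
    cm = counts[second, np.arange(m.shape[1])]
    ok = (
        (depth >= min_depth)
        & (cm >= min_count)
        & (cm >= min_fraction * depth)
    )
    for col in np.flatnonzero(ok):
        sites.append(
            HetSite(
                pos=pileup.region_start + int(col),
                allele_a=int(top[col]),
                allele_b=int(second[col]),
                count_a=int(cn[col]),
                count_b=int(cm[col]),
            )
        )
    return sites


def cluster_alleles(
    pileup: PileupMatrix,
    het_sites: list[HetSite],
    amplicon_id: str = "",
    min_reads: int = 10,
) -> list[AlleleCluster]:
    """Split reads into <= 2 allele groups by their het-site allele vectors.

    With no het site all reads form a single cluster.  Otherwise site
    polarities are phased by adjacent-site linkage, reads are assigned by
    agreement with the phased profile versus its mirror, and membership is
    refined with one majority-signature reassignment pass; the procedure is
    deterministic given read input order.
    """
    n = pileup.n_reads
    read_ids = [a.read_id for a in pileup.alignments]
    if not het_sites:
        c = AlleleCluster(amplicon_id, 0, list(range(n)), read_ids, {},
                          low_support=n < min_reads)
        return [c]

    # substitution sites are the reliable clustering currency: indel columns
    # suffer from degenerate aligner gap placement (a homozygous indel can
    # masquerade as a het column), so they are used only when no SNV site
    # exists at all
    snv_sites = [s for s in het_sites if s.allele_a != _DEL and s.allele_b != _DEL]
    if snv_sites:
        het_sites = snv_sites

    cols = np.array([s.pos - pileup.region_start for s in het_sites])
    sub = pileup.site_codes[:, cols]  # (n_reads, n_sites)
    a = np.array([s.allele_a for s in het_sites])
    b = np.array([s.allele_b for s in het_sites])
    # map to 0 / 1 / -1 (other or missing)
    vec = np.full(sub.shape, -1, dtype=np.int8)
    vec[sub == a] = 0
    vec[sub == b] = 1

    # anchor a consistent allele polarity across sites by transitive
    # linkage: reads covering two adjacent sites vote on whether their
    # major alleles ride on the same haplotype.  Reads then split by
    # agreement with the resulting profile versus its mirror — this keeps
    # distant site blocks (bridged only through chains of reads) in phase.
    n_sites = len(het_sites)
    polarity = np.ones(n_sites, dtype=np.int8)
    for k in range(n_sites - 1):
        both = (vec[:, k] >= 0) & (vec[:, k + 1] >= 0)
        same = int((vec[both, k] == vec[both, k + 1]).sum())
        diff_n = int(both.sum()) - same
        link = 1 if same >= diff_n else -1
        polarity[k + 1] = polarity[k] * link
    profile = np.where(polarity == 1, 0, 1).astype(np.int8)
    mirror = (1 - profile).astype(np.int8)

    def assign(signatures):
        members: list[list[int]] = [[], []]
        for r in range(n):
            scores = []
            for sig in signatures:
                both = (vec[r] >= 0) & (sig >= 0)
                scores.append(int((vec[r][both] == sig[both]).sum()) - int(both.sum()))
            members[0 if scores[0] >= scores[1] else 1].append(r)
        return members

    members = assign([profile, mirror])
    # one refinement pass with majority signatures
    sigs = []
    for mem in members:
        if mem:
            sub_m = vec[mem]
            sig = np.full(len(het_sites), -1, dtype=np.int8)
            n0 = ((sub_m == 0).sum(axis=0))
            n1 = ((sub_m == 1).sum(axis=0))
            sig[n0 > n1] = 0
            sig[n1 > n0] = 1
            sigs.append(sig)
        else:
            sigs.append(np.full(len(het_sites), -1, dtype=np.int8))
    members = assign(sigs)
    if not members[0] or not members[1]:
        c = AlleleCluster(amplicon_id, 0, list(range(n)), read_ids, {},
                          low_support=n < min_reads)
        return [c]

    out = []
    for cid, mem in enumerate(members):
        sig_dict = {}
        sub_m = vec[mem]
        n0 = (sub_m == 0).sum(axis=0)
        n1 = (sub_m == 1).sum(axis=0)
        for s_idx, site in enumerate(het_sites):
            code = site.allele_a if n0[s_idx] >= n1[s_idx] else site.allele_b
            sig_dict[site.pos] = code
        out.append(
            AlleleCluster(
                amplicon_id, cid, mem, [read_ids[r] for r in mem], sig_dict,
                low_support=len(mem) < min_reads,
            )
        )
    return out


def call_consensus(
    pileup: PileupMatrix,
    cluster: AlleleCluster,
    reference: str,
    min_depth: int = 4,
) -> Consensus:
    """Per-column plurality consensus of a cluster.

    Ties and columns below ``min_depth`` fall back to the reference base —
    the no-call-as-reference policy that prefers missing a variant over
    inventing one from one or two noisy reads.
    """
    if not cluster.member_indices:
        raise ValueError("cannot call a consensus for an empty cluster")
    start = pileup.region_start
    m = pileup.codes[cluster.member_indices]
    ncol = m.shape[1]
    counts = np.zeros((5, ncol), dtype=np.int32)
    for code in range(5):
        counts[code] = (m == code).sum(axis=0)
    depth = counts.sum(axis=0)
    ref_codes = _codes_of(reference[start - 1 : start + ncol - 1]).astype(np.int64)
    ref_codes[ref_codes < 0] = 0
    best = counts.max(axis=0)
    # plurality winner; ties and thin columns fall back to the reference
    winner = np.where(
        counts[ref_codes, np.arange(ncol)] == best, ref_codes, np.argmax(counts, axis=0)
    )
    thin = depth < min_depth
    winner[thin] = ref_codes[thin]

    # insertion consensus: majority of covering reads must carry an insertion
    ins_at: dict[int, str] = {}
    ins_counter: dict[int, Counter] = {}
    for r in cluster.member_indices:
        for anchor, seq in pileup.insertions[r].items():
            ins_counter.setdefault(anchor, Counter())[seq] += 1
    for anchor, ctr in ins_counter.items():
        col = anchor - start
        if not (0 <= col < ncol) or depth[col] < min_depth:
            continue
        total = sum(ctr.values())
        if total * 2 > depth[col]:
            seq, _ = min(ctr.items(), key=lambda kv: (-kv[1], kv[0]))
            ins_at[anchor] = seq

    chars: list[str] = []
    positions: list[int] = []
    support: list[float] = []
    for col in range(ncol):
        w = int(winner[col])
        frac = counts[w, col] / depth[col] if depth[col] else 0.0
        if w != _DEL:
            chars.append(_BASES[w])
            positions.append(start + col)
            support.append(frac)
        pos = start + col
        if pos in ins_at:
            for ch in ins_at[pos]:
                chars.append(ch)
                positions.append(pos)
                support.append(1.0)
    return Consensus(
        amplicon_id=cluster.amplicon_id,
        cluster_id=cluster.cluster_id,
        sequence="".join(chars),
        ref_start=start,
        ref_positions=np.asarray(positions, dtype=np.int64),
        support=np.asarray(support, dtype=np.float32),
        n_reads=cluster.n_reads,
        low_support=cluster.low_support,
    )


def _query_span(aln: ReadAlignment, w0: int, w1: int) -> tuple[int, int] | None:
    """Query index range aligned to reference interval [w0, w1] (1-based),
    or None when the read does not fully span it."""
    if aln.locus_start > w0 or aln.locus_end < w1:
        return None
    rpos = aln.locus_start
    qpos = 0
    q0 = q1 = None
    for length, op in aln.cigar:
        if op in "=XM":
            if q0 is None and rpos + length > w0:
                q0 = qpos + max(w0 - rpos, 0)
            if rpos + length > w1:
                q1 = qpos + (w1 - rpos) + 1
                return (q0, q1) if q0 is not None else None
            rpos += length
            qpos += length
        elif op == "D":
            if q0 is None and rpos + length > w0:
                q0 = qpos
            if rpos + length > w1:
                return (q0, qpos) if q0 is not None else None
            rpos += length
        else:  # I
            qpos += length
    return None


def refine_indel_calls(
    variants: list[tuple[int, str, str]],
    pileup: PileupMatrix,
    cluster: AlleleCluster,
    reference: str,
    window: int = 25,
    max_hypotheses: int = 8,
) -> list[tuple[int, str, str]]:
    """Re-decide non-SNV calls by per-read hypothesis realignment.

    Column votes degrade around indels: errors near the event make each
    read's aligner decomposition idiosyncratic.  Here every member read
    votes for the local haplotype hypothesis (reference window, or the
    window with one observed event applied) closest to it in edit
    distance; the winning hypothesis replaces the call, and a reference
    win removes it.  The distance gap between hypotheses is the event
    size, so votes are decisive even for reads carrying unrelated errors.
    """
    import edlib

    refined: list[tuple[int, str, str]] = []
    for pos, r, a in variants:
        if len(r) == 1 and len(a) == 1:
            refined.append((pos, r, a))
            continue
        end = pos + len(r) - 1 if r else pos
        w0 = max(1, pos - window)
        w1 = min(len(reference), end + window)
        ref_window = reference[w0 - 1 : w1]

        # candidate events observed in member reads around the call
        cand: Counter = Counter()
        cand[(pos, r, a)] += 0  # the call itself is always a hypothesis
        for row in cluster.member_indices:
            for e in pileup.events[row] or ():
                ep, er, _ = e
                ee = ep + len(er) - 1 if er else ep
                if ep >= w0 + 2 and ee <= w1 - 2 and (len(er) != 1 or len(_) != 1):
                    cand[e] += 1
        hyps: list[tuple[tuple[int, str, str] | None, str]] = [(None, ref_window)]
        for e, _n in sorted(cand.items(), key=lambda kv: (-kv[1], repr(kv[0])))[
            :max_hypotheses
        ]:
            ep, er, ea = e
            if not (w0 <= ep and (ep + len(er) - 1 if er else ep) <= w1):
                continue
            off = ep - w0  # 0-based offset in window of first affected base
            if er:
                seq = ref_window[:off] + ea + ref_window[off + len(er) :]
            else:  # insertion after ep
                seq = ref_window[: off + 1] + ea + ref_window[off + 1 :]
            hyps.append((e, seq))

        votes: Counter = Counter()
        for row in cluster.member_indices:
            span = _query_span(pileup.alignments[row], w0, w1)
            if span is None:
                continue
            seg = pileup.alignments[row].query[span[0] : span[1]]
            best_i, best_d = 0, None
            for i, (_e, seq) in enumerate(hyps):
                d = edlib.align(seg, seq, mode="NW")["editDistance"]
                if best_d is None or d < best_d:
                    best_i, best_d = i, d
            votes[best_i] += 1
        if not votes:
            refined.append((pos, r, a))
            continue
        win_i = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        winner = hyps[win_i][0]
        if winner is not None:
            refined.append(winner)
        # reference won: drop the call
    out: list[tuple[int, str, str]] = []
    for v in refined:
        if v not in out:
            out.append(v)
    return out
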