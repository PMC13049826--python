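"""Exact k-mer anchoring of a query against the locus reference.

Shared machinery for the haplotype differ and the split-read junction
caller: unique reference k-mers are indexed once; query k-mers sampled at a
stride vote for alignment diagonals; runs of collinear hits become anchor
segments.  A query spanning a large deletion produces two segments whose
reference gap exceeds the segment drift, which is the split-read signal.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["KmerIndex", "Segment", "chain_query", "build_index"]


@dataclass(frozen=True)
class Segment:
    """A collinear run of exact k-mer hits.

    Attributes are 0-based: query positions of the first/last hit, and the
    local diagonals (ref_pos - query_pos) at the segment ends; ``q_end`` is
    the query position one past the last matched k-mer.
    """

    q_start: int
    q_end: int
    diag_start: int
    diag_end: int
    n_hits: int

    @property
    def ref_start(self) -> int:
        return self.q_start + self.diag_start

    @property
    def ref_end(self) -> int:
        return self.q_end + self.diag_end


class KmerIndex:
    """Unique-k-mer index of one reference sequence."""

    def __init__(self, sequence: str, k: int = 32):
        self.sequence = sequence
        self.k = k
        index: dict[bytes, int] = {}
        dup: set[bytes] = set()
        raw = sequence.encode("ascii")
        for i in range(len(raw) - k + 1):
            km = raw[i : i + k]
            if km in dup:
                continue
            if km in index:
                del index[km]
                dup.add(km)
            else:
                index[km] = i
        self._index = index

    def lookup(self, kmer: bytes) -> int | None:
        return self._index.get(kmer)


def build_index(sequence: str, k: int = 32) -> KmerIndex:
    return KmerIndex(sequence, k)


def chain_query(
    query: str,
    index: KmerIndex,
    stride: int = 8,
    max_drift: int = 40,
    min_hits: int = 3,
) -> list[Segment]:
    """Chain sampled exact k-mer hits of `query` into collinear segments.

    A new segment starts whenever the diagonal jumps by more than
    ``max_drift`` (an indel larger than read-error drift) or the reference
    position steps backwards.  Segments with fewer than ``min_hits`` hits
    are discarded as spurious.
    """
    k = index.k
    raw = query.encode("ascii")
    hits: list[tuple[int, int]] = []  # (query_pos, ref_pos)
    for i in range(0, max(len(raw) - k + 1, 0), stride):
        r = index.lookup(raw[i : i + k])
        if r is not None:
            hits.append((i, r))
    segments: list[Segment] = []
    cur: list[tuple[int, int]] = []
    for q, r in hits:
        if cur:
            pq, pr = cur[-1]
            if r <= pr or abs((r - q) - (pr - pq)) > max_drift:
                if len(cur) >= min_hits:
                    segments.append(_to_segment(cur, k))
                cur = []
        cur.append((q, r))
    if len(cur) >= min_hits:
        segments.append(_to_segment(cur, k))
    return segments


def _to_segment(run: list[tuple[int, int]], k: int) -> Segment:
    q0, r0 = run[0]
    q1, r1 = run[-1]
    return Segment(
        q_start=q0,
        q_end=q1 + k,
        diag_start=r0 - q0,
        diag_end=r1 - q1,
        n_hits=len(run),
    )
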