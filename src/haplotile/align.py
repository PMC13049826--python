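"""Read-to-locus alignment and amplicon assignment.

Alignment is seed-and-extend against the known locus: a short read prefix
anchors the read (both orientations tried), then the full read is aligned
with edlib inside a padded window.  The contract is the
:class:`ReadAlignment` record — locus span, CIGAR-style operations, identity
— not the engine.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import edlib

from .pcr import revcomp
from .simulate import AmpliconPanel, SimulatedRead

__all__ = ["ReadAlignment", "align_read", "align_reads", "assign_amplicon"]

_CIG_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ReadAlignment:
    """One read aligned to the locus (forward-strand orientation)."""

    read_id: str
    query: str                      # read sequence, locus-forward orientation
    locus_start: int                # 1-based first aligned reference base
    locus_end: int                  # 1-based last aligned reference base
    strand: str                     # original read orientation
    cigar: list[tuple[int, str]]    # (length, op) with ops =/X/I/D
    identity: float
    amplicon_id: str | None = None
    meta: SimulatedRead | None = field(default=None, repr=False)

    @property
    def aligned_span(self) -> int:
        return self.locus_end - self.locus_start + 1


def _parse_cigar(cig: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIG_RE.findall(cig)]


def align_read(
    read: SimulatedRead | str,
    reference: str,
    anchor_len: int = 800,
    min_identity: float = 0.7,
) -> ReadAlignment | None:
    """Align one read; returns None when no credible placement exists.

    The identity floor sits well above the ~0.5 identity of a random
    placement and well below the worst credible long-read identity.
    """
    if isinstance(read, SimulatedRead):
        seq, read_id, meta = read.sequence, read.read_id, read
    else:
        seq, read_id, meta = read, "read", None
    best = None
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        anchor = oriented[: min(anchor_len, len(oriented))]
        res = edlib.align(anchor, reference, mode="HW", task="locations")
        if res["editDistance"] < 0 or not res["locations"]:
            continue
        if best is None or res["editDistance"] < best[0]:
            best = (res["editDistance"], strand, oriented, res["locations"][0])
    if best is None:
        return None
    anchor_dist, strand, oriented, (astart, _aend) = best
    if anchor_dist > len(oriented[:anchor_len]) * (1 - min_identity):
        return None
    pad = max(500, len(oriented) // 5)
    w0 = max(0, astart - pad)
    w1 = min(len(reference), astart + len(oriented) + pad)
    res = edlib.align(oriented, reference[w0:w1], mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    aln_len = max(len(oriented), loc[1] - loc[0] + 1)
    identity = 1.0 - res["editDistance"] / aln_len
    if identity < min_identity:
        return None
    return ReadAlignment(
        read_id=read_id,
        query=oriented,
        locus_start=w0 + loc[0] + 1,
        locus_end=w0 + loc[1] + 1,
        strand=strand,
        cigar=_parse_cigar(res["cigar"]),
        identity=identity,
        meta=meta,
    )


def align_reads(reads, reference: str, **kw) -> list[ReadAlignment]:
    out = []
    for r in reads:
        a = align_read(r, reference, **kw)
        if a is not None:
            out.append(a)
    return out


def assign_amplicon(alignment: ReadAlignment, panel: AmpliconPanel) -> str | None:
    """Assign a read to the amplicon holding the larger aligned fraction.

    Reads in overlap zones go to the amplicon containing more of the aligned
    span; reads overlapping no amplicon stay unassigned.
    """
    best_name, best_ov = None, 0
    for amp in panel:
        lo = max(alignment.locus_start, amp.start)
        hi = min(alignment.locus_end, amp.end)
        ov = hi - lo + 1
        if ov > best_ov:
            best_name, best_ov = amp.name, ov
    if best_ov <= 0:
        return None
    alignment.amplicon_id = best_name
    return best_name
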