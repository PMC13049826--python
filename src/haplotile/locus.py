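"""Reference locus, transcript coordinate system and region annotation.

The locus is a single forward-strand gene of ~77 kb with 15 exons of which
12 (exons 3..14) are coding; translation initiates inside exon 3.  All
public coordinates are 1-based inclusive; internal slicing is 0-based
half-open.

Coding (c.) coordinates follow HGVS with one documented simplification for
this gene family's literature: positions 5' of the translation start that
lie upstream of the start-codon exon are written ``c.1-K`` where K is the
*linear genomic* distance to c.1.  Standard HGVS would express these as
offsets from noncoding-exon anchors, but the source nomenclature for the
large intron-1 deletion-insertion uses the linear convention, so the
renderer and parser reproduce it (see docs/methods.md).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "LocusReference",
    "TranscriptModel",
    "CoordinateError",
    "g_to_c",
    "c_to_g",
]

_DNA_RE = re.compile(r"^[ACGT]+$")


class CoordinateError(ValueError):
    """A genomic or transcript coordinate outside the modelled locus."""


@dataclass(frozen=True)
class LocusReference:
    """Reference sequence of the locus (uppercase A/C/G/T)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not _DNA_RE.match(self.sequence):
            raise ValueError("reference sequence must be uppercase A/C/G/T")
        if len(self.sequence) < 60_000:
            raise ValueError(
                f"locus too short ({len(self.sequence)} bp); expected a full-length gene"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """1-based single-base accessor."""
        if not 1 <= pos <= self.length:
            raise CoordinateError(f"position {pos} outside locus 1..{self.length}")
        return self.sequence[pos - 1]

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive substring."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(f"span {start}..{end} outside locus 1..{self.length}")
        return self.sequence[start - 1 : end]


@dataclass(frozen=True)
class TranscriptModel:
    """Forward-strand transcript: exon intervals plus CDS bounds.

    Parameters
    ----------
    exons:
        Ordered, non-overlapping (start, end) pairs, 1-based inclusive.
    cds_start:
        Locus position of c.1 (first base of the ATG), inside exon 3.
    cds_end:
        Locus position of the last coding base (inside the last coding exon).
    """

    exons: tuple[tuple[int, int], ...]
    cds_start: int
    cds_end: int
    # index (0-based) of the exon containing cds_start; derived, cached
    _cds_exon_index: int = field(init=False, repr=False, default=-1)

    def __post_init__(self) -> None:
        exons = tuple((int(s), int(e)) for s, e in self.exons)
        object.__setattr__(self, "exons", exons)
        if len(exons) != 15:
            raise ValueError(f"expected 15 exons, got {len(exons)}")
        for (s, e), (s2, _) in zip(exons, exons[1:]):
            if not (s <= e < s2):
                raise ValueError("exons must be sorted, non-overlapping")
        idx = self.exon_index(self.cds_start)
        if idx != 2:
            raise ValueError("translation start must lie inside exon 3")
        object.__setattr__(self, "_cds_exon_index", idx)
        if self.exon_index(self.cds_end) is None:
            raise ValueError("cds_end must be exonic")

    # -- basic interval queries -------------------------------------------

    def exon_index(self, pos: int) -> int | None:
        """0-based index of the exon containing pos, else None."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos <= e:
                return i
        return None

    def intron_index(self, pos: int) -> int | None:
        """0-based index of the intron containing pos (intron i follows exon i)."""
        for i in range(len(self.exons) - 1):
            if self.exons[i][1] < pos < self.exons[i + 1][0]:
                return i
        return None

    @property
    def coding_exon_indices(self) -> list[int]:
        return [
            i
            for i, (s, e) in enumerate(self.exons)
            if e >= self.cds_start and s <= self.cds_end
        ]

    def coding_length(self) -> int:
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                n += hi - lo + 1
        return n

    def coding_pos(self, pos: int) -> int | None:
        """c.N for an exonic position within the CDS, else None."""
        if not (self.cds_start <= pos <= self.cds_end):
            return None
        if self.exon_index(pos) is None:
            return None
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, min(pos, self.cds_end))
            if lo <= hi:
                n += hi - lo + 1
            if e >= pos:
                break
        return n

    def coding_pos_to_g(self, c: int) -> int:
        """Inverse of :meth:`coding_pos` for 1 <= c <= CDS length."""
        if c < 1:
            raise CoordinateError(f"coding position must be >= 1, got {c}")
        remaining = c
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo > hi:
                continue
            span = hi - lo + 1
            if remaining <= span:
                return lo + remaining - 1
            remaining -= span
        raise CoordinateError(f"c.{c} beyond CDS length {self.coding_length()}")

    def utr3_pos(self, pos: int) -> int | None:
        """c.*N for an exonic position 3' of the CDS, else None."""
        if pos <= self.cds_end or self.exon_index(pos) is None:
            return None
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_end + 1), min(e, pos)
            if lo <= hi:
                n += hi - lo + 1
            if e >= pos:
                break
        return n

    def utr3_pos_to_g(self, star: int) -> int:
        remaining = star
        for s, e in self.exons:
            lo, hi = max(s, self.cds_end + 1), e
            if lo > hi:
                continue
            span = hi - lo + 1
            if remaining <= span:
                return lo + remaining - 1
            remaining -= span
        raise CoordinateError(f"c.*{star} beyond transcript 3' UTR")

    # -- annotation helpers ------------------------------------------------

    def region_label(self, pos: int) -> str:
        """``exon N`` / ``intron N`` / ``5'UTR`` / ``3'UTR`` / ``upstream`` / ``downstream``."""
        i = self.exon_index(pos)
        if i is not None:
            if pos < self.cds_start:
                return "5'UTR"
            if pos > self.cds_end:
                return "3'UTR"
            return f"exon {i + 1}"
        j = self.intron_index(pos)
        if j is not None:
            return f"intron {j + 1}"
        if pos < self.exons[0][0]:
            return "upstream"
        return "downstream"

    def boundary_distance(self, pos: int) -> int:
        """Distance (bp) to the nearest exon-intron boundary; 0 if exonic."""
        if self.exon_index(pos) is not None:
            return 0
        best = None
        for s, e in self.exons:
            d = min(abs(pos - s), abs(pos - e))
            best = d if best is None else min(best, d)
        return best if best is not None else 0


# ---------------------------------------------------------------------------
# g. <-> c. coordinate strings


def g_to_c(pos: int, transcript: TranscriptModel, locus_length: int | None = None) -> str:
    """Render a locus position as a c.-space coordinate string.

    Coding exonic positions become ``c.N``; 5'UTR positions inside the
    start-codon exon become ``c.-N``; positions upstream of that exon use the
    linear convention ``c.1-K`` (K = genomic distance to c.1); 3'UTR exonic
    positions become ``c.*N``; intronic positions downstream of the start
    exon use nearest-exon offsets ``c.N+k`` / ``c.N-k``.
    """
    if pos < 1 or (locus_length is not None and pos > locus_length):
        raise CoordinateError(f"position {pos} outside locus")
    t = transcript
    start_exon_s, _ = t.exons[t._cds_exon_index]

    if pos < t.cds_start:
        if pos >= start_exon_s:
            return f"c.-{t.cds_start - pos}"
        return f"c.1-{t.cds_start - pos}"

    c = t.coding_pos(pos)
    if c is not None:
        return f"c.{c}"

    star = t.utr3_pos(pos)
    if star is not None:
        return f"c.*{star}"

    j = t.intron_index(pos)
    if j is not None:
        up_end = t.exons[j][1]
        down_start = t.exons[j + 1][0]
        d_up = pos - up_end
        d_down = down_start - pos
        if d_up <= d_down:
            return f"{_exonic_label(up_end, t)}+{d_up}"
        return f"{_exonic_label(down_start, t)}-{d_down}"

    # 3' of the last exon: offset from the transcript end
    last_end = t.exons[-1][1]
    return f"{_exonic_label(last_end, t)}+{pos - last_end}"


def _exonic_label(pos: int, t: TranscriptModel) -> str:
    """c.-string for an exonic anchor position (no intronic offset)."""
    if pos < t.cds_start:
        return f"c.-{t.cds_start - pos}"
    c = t.coding_pos(pos)
    if c is not None:
        return f"c.{c}"
    star = t.utr3_pos(pos)
    if star is not None:
        return f"c.*{star}"
    raise CoordinateError(f"position {pos} is not exonic")


_C_COORD_RE = re.compile(
    r"""^c\.
        (?P<anchor>\*?-?\d+)          # c.N, c.-N or c.*N anchor
        (?P<offset>[+-]\d+)?          # optional intronic / linear offset
        $""",
    re.X,
)


def c_to_g(cstr: str, transcript: TranscriptModel) -> int:
    """Parse a c.-space coordinate string back to a locus position."""
    s = cstr.replace(" ", "")
    if not s.startswith("c."):
        s = "c." + s
    m = _C_COORD_RE.match(s)
    if m is None:
        raise CoordinateError(f"malformed c. coordinate: {cstr!r}")
    anchor_s = m.group("anchor")
    offset = int(m.group("offset")) if m.group("offset") else 0
    t = transcript

    if anchor_s.startswith("*"):
        g = t.utr3_pos_to_g(int(anchor_s[1:]))
    elif anchor_s.startswith("-"):
        g = t.cds_start - int(anchor_s[1:])
        if g < 1:
            raise CoordinateError(f"{cstr!r} lies upstream of the locus")
        if offset:
            raise CoordinateError(f"offsets from 5'UTR anchors unsupported: {cstr!r}")
        return g
    else:
        anchor = int(anchor_s)
        if anchor == 1 and offset < 0:
            # linear upstream convention: c.1-K is K genomic bases before c.1
            g = t.cds_start + offset
            if g < 1:
                raise CoordinateError(f"{cstr!r} lies upstream of the locus")
            return g
        g = t.coding_pos_to_g(anchor)
    return g + offset
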