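"""Variant representation, HGVS parsing/naming, normalization, application.

A :class:`Variant` is a replacement edit on the reference locus:
``pos`` is the 1-based position of the first replaced base (for pure
insertions, the base *after which* the new sequence is inserted and
``ref == ""``).  Supported HGVS forms are the ones used in the source
nomenclature for this locus: substitutions, del[SEQ], dup[SEQ], ins,
and delins, in c. or g. space, including the nonstandard single-position
multi-base deletion alias (``c.1227delTATTGTGCCTAT``).

Normalization trims the common affix of ref/alt and shifts pure
insertions/deletions to their 3'-most (rightmost) equivalent placement,
so any two descriptions of the same edit compare equal.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .locus import LocusReference, TranscriptModel, c_to_g, g_to_c

__all__ = [
    "Variant",
    "VariantKind",
    "HGVSParseError",
    "VariantConflictError",
    "parse_hgvs",
    "format_hgvs_c",
    "format_hgvs_g",
    "normalize_variant",
    "apply_variants",
    "CoordinateMap",
    "five_prime_alias",
]


class VariantKind(str, Enum):
    SNV = "SNV"
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    DELINS = "DELINS"


class HGVSParseError(ValueError):
    pass


class VariantConflictError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class Variant:
    """A replacement edit in locus (g.) coordinates, 1-based."""

    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref == "" and self.alt == "":
            raise ValueError("a variant must change the sequence")
        if self.pos < 1:
            raise ValueError("variant position must be >= 1")

    @property
    def end(self) -> int:
        """1-based last replaced base; == pos for insertions (anchor base)."""
        return self.pos + max(len(self.ref), 1) - 1 if self.ref else self.pos

    @property
    def kind(self) -> VariantKind:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return VariantKind.SNV
        if self.alt == "":
            return VariantKind.DEL
        if self.ref == "":
            return VariantKind.INS
        return VariantKind.DELINS

    @property
    def span(self) -> int:
        return len(self.ref)

    def validate(self, ref: LocusReference) -> None:
        if self.ref:
            found = ref.slice(self.pos, self.pos + len(self.ref) - 1)
            if found != self.ref:
                raise VariantConflictError(
                    f"reference mismatch at {self.pos}: variant says {self.ref!r}, "
                    f"locus has {found!r}"
                )
        elif not 1 <= self.pos <= ref.length:
            raise VariantConflictError(f"insertion anchor {self.pos} outside locus")


# ---------------------------------------------------------------------------
# normalization


def normalize_variant(v: Variant, ref: LocusReference) -> Variant:
    """Canonical (3'-most, minimal) representation of an edit.

    Two variants producing identical edited sequences normalize to the same
    canonical form: the common prefix/suffix of ref/alt is trimmed, then
    pure insertions/deletions are shifted right while the flanking sequence
    permits.  SNVs are fixed points.
    """
    v.validate(ref)
    pos, r, a = v.pos, v.ref, v.alt

    # trim common suffix then prefix
    while r and a and r[-1] == a[-1]:
        r, a = r[:-1], a[:-1]
    while r and a and r[0] == a[0]:
        r, a = r[1:], a[1:]
        pos += 1

    seq = ref.sequence
    if a == "" and r:  # pure deletion: shift right while next base repeats
        while pos + len(r) <= ref.length and seq[pos + len(r) - 1] == r[0]:
            r = r[1:] + seq[pos + len(r) - 1]
            pos += 1
    elif r == "" and a:  # pure insertion (anchored after `pos`)
        while pos + 1 <= ref.length and seq[pos] == a[0]:
            a = a[1:] + seq[pos]
            pos += 1
    if r == "" and a == "":
        raise VariantConflictError("variant is a no-op on this reference")
    return Variant(pos=pos, ref=r, alt=a)


def five_prime_alias(v: Variant, ref: LocusReference) -> Variant:
    """5'-most equivalent placement (the alias some reports print)."""
    v = normalize_variant(v, ref)
    pos, r, a = v.pos, v.ref, v.alt
    seq = ref.sequence
    if a == "" and r:
        while pos >= 2 and seq[pos - 2] == r[-1]:
            r = seq[pos - 2] + r[:-1]
            pos -= 1
    elif r == "" and a:
        while pos >= 1 and seq[pos - 1] == a[-1]:
            a = seq[pos - 1] + a[:-1]
            pos -= 1
    return Variant(pos=pos, ref=r, alt=a)


def is_duplication(v: Variant, ref: LocusReference) -> bool:
    """True when an insertion duplicates the reference bases just 5' of it."""
    if v.ref != "" or v.alt == "":
        return False
    n = len(v.alt)
    if v.pos - n + 1 < 1:
        return False
    return ref.slice(v.pos - n + 1, v.pos) == v.alt


# ---------------------------------------------------------------------------
# HGVS parsing

_WS = re.compile(r"\s+")

_COORD = r"(?:\*?-?\d+(?:[+-]\d+)?)"
_HGVS_RE = re.compile(
    rf"""^(?P<space>[cg])\.
        (?P<p1>{_COORD})
        (?:_(?:[cg]\.)?(?P<p2>{_COORD}))?
        (?P<op>
            (?P<refb>[ACGTacgt])>(?P<altb>[ACGTacgt])      # substitution
          | delins(?P<dinseq>[ACGTacgt]+)
          | del(?P<delseq>[ACGTacgt]*)
          | dup(?P<dupseq>[ACGTacgt]*)
          | ins(?P<insseq>[ACGTacgt]+)
        )$""",
    re.X,
)


def _coord_to_g(token: str, space: str, transcript: TranscriptModel | None) -> int:
    if space == "g":
        m = re.match(r"^\d+$", token)
        if m is None:
            raise HGVSParseError(f"bad g. coordinate {token!r}")
        return int(token)
    if transcript is None:
        raise HGVSParseError("a transcript model is required for c. coordinates")
    return c_to_g("c." + token, transcript)


def parse_hgvs(
    text: str,
    transcript: TranscriptModel | None = None,
    ref: LocusReference | None = None,
) -> Variant:
    """Parse a c. or g. HGVS description into a g-space :class:`Variant`.

    When `ref` is given, deletion/duplication forms without an explicit
    sequence are filled from the reference and stated sequences are checked.
    """
    s = _WS.sub("", text)
    m = _HGVS_RE.match(s)
    if m is None:
        raise HGVSParseError(f"unsupported HGVS syntax: {text!r}")
    space = m.group("space")
    g1 = _coord_to_g(m.group("p1"), space, transcript)
    g2 = _coord_to_g(m.group("p2"), space, transcript) if m.group("p2") else None

    if m.group("refb"):
        if g2 is not None:
            raise HGVSParseError(f"substitution cannot carry a range: {text!r}")
        return Variant(pos=g1, ref=m.group("refb").upper(), alt=m.group("altb").upper())

    if m.group("dinseq") is not None:
        end = g2 if g2 is not None else g1
        if end < g1:
            raise HGVSParseError(f"inverted range in {text!r}")
        rseq = ref.slice(g1, end) if ref is not None else "N" * (end - g1 + 1)
        return Variant(pos=g1, ref=rseq, alt=m.group("dinseq").upper())

    if "del" in m.group("op") and m.group("delseq") is not None:
        stated = m.group("delseq").upper()
        if g2 is None and len(stated) > 1:
            # single-position multi-base alias: c.1227delTATTGTGCCTAT
            end = g1 + len(stated) - 1
        else:
            end = g2 if g2 is not None else g1
        if end < g1:
            raise HGVSParseError(f"inverted range in {text!r}")
        if stated and len(stated) != end - g1 + 1:
            raise HGVSParseError(
                f"deleted sequence length {len(stated)} does not match span in {text!r}"
            )
        rseq = stated or (
            ref.slice(g1, end) if ref is not None else "N" * (end - g1 + 1)
        )
        return Variant(pos=g1, ref=rseq, alt="")

    if m.group("dupseq") is not None:
        stated = m.group("dupseq").upper()
        end = g2 if g2 is not None else g1
        span = end - g1 + 1
        if stated and len(stated) != span:
            raise HGVSParseError(
                f"duplicated sequence length mismatch in {text!r}"
            )
        dseq = stated or (ref.slice(g1, end) if ref is not None else None)
        if dseq is None:
            raise HGVSParseError(f"dup without sequence needs a reference: {text!r}")
        # a duplication is an insertion of the repeated unit after its 3' copy
        return Variant(pos=end, ref="", alt=dseq)

    if m.group("insseq") is not None:
        # ins between p1 and p2 (p2 optional in the source's shorthand)
        if g2 is not None and g2 != g1 + 1:
            raise HGVSParseError(f"ins anchors must be adjacent in {text!r}")
        return Variant(pos=g1, ref="", alt=m.group("insseq").upper())

    raise HGVSParseError(f"unsupported HGVS syntax: {text!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# HGVS naming


def _c(pos: int, t: TranscriptModel) -> str:
    return g_to_c(pos, t)


def format_hgvs_c(v: Variant, transcript: TranscriptModel, ref: LocusReference) -> str:
    """Canonical c.-space name of a (normalized) variant."""
    v = normalize_variant(v, ref)
    t = transcript
    k = v.kind
    if k is VariantKind.SNV:
        return f"{_c(v.pos, t)}{v.ref}>{v.alt}"
    if k is VariantKind.DEL:
        if len(v.ref) == 1:
            return f"{_c(v.pos, t)}del{v.ref}"
        return f"{_c(v.pos, t)}_{_strip_c(_c(v.end, t))}del{v.ref}"
    if k is VariantKind.INS:
        if is_duplication(v, ref):
            n = len(v.alt)
            if n == 1:
                return f"{_c(v.pos, t)}dup{v.alt}"
            return f"{_c(v.pos - n + 1, t)}_{_strip_c(_c(v.pos, t))}dup{v.alt}"
        return f"{_c(v.pos, t)}_{_strip_c(_c(v.pos + 1, t))}ins{v.alt}"
    # delins; keep the second c. prefix when the left end uses the linear
    # upstream convention, matching the nomenclature used for this locus
    left, right = _c(v.pos, t), _c(v.end, t)
    if re.match(r"^c\.1-\d+$", left):
        return f"{left}_{right}delins{v.alt}"
    return f"{left}_{_strip_c(right)}delins{v.alt}"


def _strip_c(s: str) -> str:
    return s[2:] if s.startswith("c.") else s


def format_hgvs_g(v: Variant, ref: LocusReference, prefix: str = "g.") -> str:
    """Canonical g.-space name of a (normalized) variant."""
    v = normalize_variant(v, ref)
    k = v.kind
    if k is VariantKind.SNV:
        return f"{prefix}{v.pos}{v.ref}>{v.alt}"
    if k is VariantKind.DEL:
        if len(v.ref) == 1:
            return f"{prefix}{v.pos}del{v.ref}"
        return f"{prefix}{v.pos}_{v.end}del{v.ref}"
    if k is VariantKind.INS:
        if is_duplication(v, ref):
            n = len(v.alt)
            if n == 1:
                return f"{prefix}{v.pos}dup{v.alt}"
            return f"{prefix}{v.pos - n + 1}_{v.pos}dup{v.alt}"
        return f"{prefix}{v.pos}_{v.pos + 1}ins{v.alt}"
    return f"{prefix}{v.pos}_{v.end}delins{v.alt}"


# ---------------------------------------------------------------------------
# application


@dataclass(frozen=True)
class CoordinateMap:
    """Monotone map from reference to edited-haplotype coordinates.

    ``ref_to_hap[p-1]`` is the 1-based haplotype position of reference base
    p, or -1 where p was deleted/replaced.
    """

    ref_to_hap: np.ndarray

    def __call__(self, pos: int) -> int:
        return int(self.ref_to_hap[pos - 1])


def apply_variants(
    ref: LocusReference, variants: list[Variant]
) -> tuple[str, CoordinateMap]:
    """Apply non-overlapping variants, returning the haplotype and a map.

    Variants are normalized first; overlapping pairs raise
    :class:`VariantConflictError` naming the offenders.
    """
    norm = sorted(normalize_variant(v, ref) for v in variants)
    for a, b in zip(norm, norm[1:]):
        # an insertion anchored at `pos` occupies no reference bases
        a_last = a.pos + len(a.ref) - 1 if a.ref else a.pos
        b_first = b.pos + 1 if not b.ref else b.pos
        if b_first <= a_last:
            raise VariantConflictError(f"overlapping variants: {a} and {b}")

    pieces: list[str] = []
    fill: list[np.ndarray] = []
    cursor = 1  # next unconsumed reference position
    hap_len = 0
    ref_to_hap = np.full(ref.length, -1, dtype=np.int64)
    for v in norm:
        if v.ref:
            keep = ref.slice(cursor, v.pos - 1) if v.pos > cursor else ""
            n = len(keep)
            if n:
                ref_to_hap[cursor - 1 : cursor - 1 + n] = np.arange(
                    hap_len + 1, hap_len + n + 1
                )
            pieces.append(keep)
            hap_len += n
            pieces.append(v.alt)
            hap_len += len(v.alt)
            cursor = v.pos + len(v.ref)
        else:  # insertion after v.pos
            keep = ref.slice(cursor, v.pos) if v.pos >= cursor else ""
            n = len(keep)
            if n:
                ref_to_hap[cursor - 1 : cursor - 1 + n] = np.arange(
                    hap_len + 1, hap_len + n + 1
                )
            pieces.append(keep)
            hap_len += n
            pieces.append(v.alt)
            hap_len += len(v.alt)
            cursor = v.pos + 1
    tail = ref.slice(cursor, ref.length) if cursor <= ref.length else ""
    if tail:
        ref_to_hap[cursor - 1 :] = np.arange(hap_len + 1, hap_len + len(tail) + 1)
    pieces.append(tail)
    return "".join(pieces), CoordinateMap(ref_to_hap=ref_to_hap)
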