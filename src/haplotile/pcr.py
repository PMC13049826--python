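"""In-silico PCR: primer-site search and product prediction.

Primer annealing is modelled as approximate string matching: a site may
carry up to ``max_mismatches`` substitutions but none within the 3'-terminal
``exact_3prime`` bases (polymerase extension requires a matched 3' end).
No thermodynamics are modelled; amplifiability is bounded only by
``max_product``, which stands in for the extension time of the cycling
programme (short-extension screening assays cannot amplify multi-kilobase
targets).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "PrimerPair",
    "PCRProduct",
    "Dropout",
    "revcomp",
    "find_primer_sites",
    "simulate_amplicon",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    name: str
    forward: str
    reverse: str  # 5'->3' on the opposite strand, as synthesized


@dataclass(frozen=True)
class PCRProduct:
    """A predicted amplicon: template substring from fwd 5' end to rev 5' end."""

    pair: PrimerPair
    start: int  # 1-based on the template
    end: int    # 1-based inclusive
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Dropout:
    """Amplification failure with a reason code: missing_site | oversize."""

    pair: PrimerPair
    reason: str


def _as_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def find_primer_sites(
    template: str,
    primer: str,
    max_mismatches: int = 2,
    exact_3prime: int = 5,
) -> list[int]:
    """1-based start positions where `primer` anneals on the forward strand."""
    t = _as_u8(template)
    p = _as_u8(primer)
    m = len(p)
    if len(t) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t, m)
    mism = (windows != p).sum(axis=1)
    cand = np.flatnonzero(mism <= max_mismatches)
    tail = p[m - exact_3prime :]
    hits = [
        int(i) + 1
        for i in cand
        if np.array_equal(windows[i, m - exact_3prime :], tail)
    ]
    return hits


@lru_cache(maxsize=4096)
def _sites_cached(template: str, primer: str, max_mm: int, exact3: int) -> tuple[int, ...]:
    return tuple(find_primer_sites(template, primer, max_mm, exact3))


def simulate_amplicon(
    hap_seq: str,
    pair: PrimerPair,
    max_product: int,
    max_mismatches: int = 2,
    exact_3prime: int = 5,
) -> PCRProduct | Dropout:
    """Predict the PCR product of a primer pair on one template molecule.

    Returns the smallest product whose forward site precedes the reverse
    site, or a :class:`Dropout` with reason ``missing_site`` (either primer
    has no convergent site) or ``oversize`` (shortest product exceeds
    ``max_product``).
    """
    if max_product <= 0:
        raise ValueError("max_product must be positive")
    f_sites = _sites_cached(hap_seq, pair.forward.upper(), max_mismatches, exact_3prime)
    r_sites = _sites_cached(
        hap_seq, revcomp(pair.reverse.upper()), max_mismatches, exact_3prime
    )
    if not f_sites or not r_sites:
        return Dropout(pair=pair, reason="missing_site")
    rlen = len(pair.reverse)
    best: tuple[int, int] | None = None  # (start, end), smallest span
    for fs in f_sites:
        for rs in r_sites:
            end = rs + rlen - 1
            if end <= fs:
                continue
            if best is None or end - fs < best[1] - best[0]:
                best = (fs, end)
    if best is None:
        return Dropout(pair=pair, reason="missing_site")
    start, end = best
    if end - start + 1 > max_product:
        return Dropout(pair=pair, reason="oversize")
    return PCRProduct(pair=pair, start=start, end=end, sequence=hap_seq[start - 1 : end])
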