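"""Haplotype-vs-reference diffing, reportability filtering, zygosity and
the cohort variant spectrum.

The differ anchors the haplotype to the reference with exact unique k-mers
and aligns only the short inter-anchor gaps; a gap whose reference or query
side exceeds the structural-variant floor is emitted directly as one delins,
which keeps a 19,971-bp deletion-insertion from fragmenting into aligner
artifacts.  Small-variant gaps are aligned globally and adjacent mismatches
within 3 bp are merged into delins events before 3' normalization.

Reportability mirrors the study's rule: exonic and 5'UTR variants plus
intronic variants within 10 bp of an exon-intron boundary; structural
variants are always reported.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import edlib
import pandas as pd

from .anchors import KmerIndex
from .locus import LocusReference
from .simulate import LocusModel
from .variants import (
    Variant,
    five_prime_alias,
    format_hgvs_c,
    format_hgvs_g,
    normalize_variant,
)

__all__ = [
    "VariantCall",
    "ZygosityCall",
    "SpectrumTable",
    "DiffError",
    "diff_haplotype",
    "annotate",
    "filter_reportable",
    "classify_zygosity",
    "tabulate_spectrum",
    "PROMOTER_VARIANT",
]

PROMOTER_VARIANT = "c.-132A>C"  # reported in prose, not a spectrum-table row


class DiffError(ValueError):
    pass


@dataclass(frozen=True)
class VariantCall:
    """An annotated, normalized variant call on one haplotype."""

    variant: Variant
    hgvs_c: str
    hgvs_g: str
    alias_c: str | None       # 5'-shifted alias when it differs (repeat context)
    region: str
    boundary_distance: int
    haplotype: str = "?"

    @property
    def is_structural(self) -> bool:
        return max(len(self.variant.ref), len(self.variant.alt)) >= 50


@dataclass(frozen=True)
class ZygosityCall:
    sample_id: str
    group: str
    zygosity: str  # homozygous | compound_heterozygous | single_heterozygous | none
    hap1_calls: tuple[str, ...]
    hap2_calls: tuple[str, ...]


_INDEX_CACHE: dict[tuple, KmerIndex] = {}


def _index_for(
    reference: LocusReference, region: tuple[int, int] | None, k: int = 32
) -> KmerIndex:
    key = (id(reference), region)
    idx = _INDEX_CACHE.get(key)
    if idx is None:
        seq = reference.slice(*region) if region else reference.sequence
        idx = KmerIndex(seq, k)
        _INDEX_CACHE[key] = idx
    return idx


def _exact_runs(query: str, index: KmerIndex) -> list[tuple[int, int, int, int]]:
    """Maximal exact-match runs (q0, q1, r0, r1), 0-based half-open, found by
    stride-1 unique-k-mer hits; runs are kept only if reference-monotone."""
    k = index.k
    raw = query.encode("ascii")
    runs: list[list[int]] = []
    prev_q = prev_r = None
    for i in range(max(len(raw) - k + 1, 0)):
        r = index.lookup(raw[i : i + k])
        if r is None:
            continue
        if prev_q == i - 1 and prev_r == r - 1:
            runs[-1][1] = i + k
            runs[-1][3] = r + k
        else:
            runs.append([i, i + k, r, r + k])
        prev_q, prev_r = i, r
    # repeat context at an edit junction lets a k-mer match both flanks, so
    # adjacent runs can overlap in query and/or reference: trim the later
    # run's start (both sides are exact matches, trimming preserves that);
    # drop runs fully consumed or jumping backwards beyond their own length
    out: list[list[int]] = []
    for q0, q1, r0, r1 in runs:
        if out:
            pq1, pr1 = out[-1][1], out[-1][3]
            d = max(pq1 - q0, pr1 - r0, 0)
            q0 += d
            r0 += d
            if q0 >= q1 or r0 >= r1:
                continue
        out.append([q0, q1, r0, r1])
    return [tuple(r) for r in out]


def _ops_to_variants(
    cigar: str, ref_seq: str, qry_seq: str, ref_offset: int, merge_gap: int = 3
) -> list[tuple[int, str, str]]:
    """Convert an edlib extended CIGAR into (pos, ref, alt) raw events,
    merging events separated by <= merge_gap matched bases into delins."""
    events: list[list] = []  # [ref_pos(1-based), ref_str, alt_str, ref_end]
    rp, qp = 0, 0
    for n_s, op in re.findall(r"(\d+)([=XIDM])", cigar):
        n = int(n_s)
        if op in "=M":
            rp += n
            qp += n
            continue
        if op == "X":
            r, a = ref_seq[rp : rp + n], qry_seq[qp : qp + n]
            rp += n
            qp += n
        elif op == "D":
            r, a = ref_seq[rp : rp + n], ""
            rp += n
        else:  # I
            r, a = "", qry_seq[qp : qp + n]
            qp += n
        # 1-based first affected base; for insertions, the anchor base before
        if r:
            pos = ref_offset + rp - len(r)
        else:
            pos = ref_offset + rp - 1
        if events:
            prev = events[-1]
            gap = (pos if r else pos + 1) - prev[3] - 1
            if gap <= merge_gap:
                f0 = prev[3] + 1 - ref_offset
                fill = ref_seq[f0 : f0 + gap]
                if prev[1] == "" and (fill or r):
                    # a pure insertion gaining reference content starts at
                    # the base after its anchor
                    prev[0] = prev[3] + 1
                prev[1] += fill + r
                prev[2] += fill + a
                prev[3] = pos - 1 + len(r) if r else pos
                continue
        events.append([pos if r else pos, r, a, pos - 1 + len(r) if r else pos])
    return [(p, r, a) for p, r, a, _ in events]


def diff_haplotype(
    haplotype: str,
    reference: LocusReference,
    region: tuple[int, int] | None = None,
    min_identity: float = 0.5,
    sv_floor: int = 50,
    merge_gap: int = 3,
) -> list[Variant]:
    """Variants whose application to `reference` reproduces `haplotype`.

    Anchored diff: stride-1 unique-k-mer hits delimit maximal exact runs;
    each inter-run gap is either globally aligned (small) or emitted as one
    delins when its reference or query side reaches ``sv_floor``.  With
    `region` set, the query is diffed against that 1-based reference
    interval only (used for amplicon consensuses); ends of the region not
    covered by the query are treated as absent data, not deletions.
    """
    if not haplotype:
        raise DiffError("empty haplotype")
    idx = _index_for(reference, region)
    offset = (region[0] - 1) if region else 0
    refseq = reference.slice(*region) if region else reference.sequence
    runs = _exact_runs(haplotype, idx)
    if not runs:
        raise DiffError("haplotype does not anchor to the reference")
    anchored = sum(q1 - q0 for q0, q1, _, _ in runs)
    if anchored < min_identity * len(haplotype):
        raise DiffError("alignment failure: identity below floor")

    raw: list[tuple[int, str, str]] = []
    bounds = []
    first, last = runs[0], runs[-1]
    if first[0] > 0 and first[2] > 0:
        # unanchored query head: align against a bounded upstream window
        r1 = first[2]
        r0 = max(0, r1 - first[0] - 50)
        bounds.append((0, first[0], r0, r1))
    for a, b in zip(runs, runs[1:]):
        bounds.append((a[1], b[0], a[3], b[2]))
    if last[1] < len(haplotype) and last[3] < len(refseq):
        q0 = last[1]
        r0 = last[3]
        r1 = min(len(refseq), r0 + (len(haplotype) - q0) + 50)
        bounds.append((q0, len(haplotype), r0, r1))

    for q0, q1, r0, r1 in bounds:
        qgap = haplotype[q0:q1]
        rgap = refseq[r0:r1]
        if not qgap and not rgap:
            continue
        if len(qgap) >= sv_floor or len(rgap) >= sv_floor:
            if rgap == "":
                raw.append((offset + r0, "", qgap))        # insertion after r0
            else:
                raw.append((offset + r0 + 1, rgap, qgap))  # delins / deletion
            continue
        if qgap == "":
            raw.append((offset + r0 + 1, rgap, ""))
            continue
        if rgap == "":
            raw.append((offset + r0, "", qgap))
            continue
        res = edlib.align(qgap, rgap, mode="NW", task="path")
        raw.extend(_ops_to_variants(res["cigar"], rgap, qgap, offset + r0 + 1, merge_gap))

    out = []
    for pos, r, a in raw:
        if r == "" and a == "":
            continue
        if pos < 1:
            continue
        out.append(normalize_variant(Variant(pos=pos, ref=r, alt=a), reference))
    return sorted(set(out))


def annotate(
    v: Variant, locus: LocusModel, haplotype: str = "?"
) -> VariantCall:
    t, ref = locus.transcript, locus.reference
    nv = normalize_variant(v, ref)
    alias = five_prime_alias(nv, ref)
    alias_c = (
        format_hgvs_c(alias, t, ref) if alias != nv and alias.kind == nv.kind else None
    )
    # region of the first affected base (insertions: the anchor base)
    pos = nv.pos
    return VariantCall(
        variant=nv,
        hgvs_c=format_hgvs_c(nv, t, ref),
        hgvs_g=format_hgvs_g(nv, ref),
        alias_c=alias_c,
        region=t.region_label(pos),
        boundary_distance=t.boundary_distance(pos),
        haplotype=haplotype,
    )


def filter_reportable(
    calls: list[VariantCall],
    boundary_bp: int = 10,
) -> list[VariantCall]:
    """The study's reporting rule: exonic/UTR variants, intronic variants
    within `boundary_bp` of an exon boundary, and all structural variants."""
    out = []
    for c in calls:
        if c.is_structural:
            out.append(c)
        elif c.region.startswith("exon") or c.region in ("5'UTR", "3'UTR"):
            out.append(c)
        elif c.region.startswith("intron") and c.boundary_distance <= boundary_bp:
            out.append(c)
    return out


def call_haplotype(
    haplotype_seq: str, locus: LocusModel, haplotype: str = "?"
) -> tuple[list[VariantCall], list[VariantCall]]:
    """Diff + annotate + filter one haplotype; returns (all, reportable)."""
    variants = diff_haplotype(haplotype_seq, locus.reference)
    calls = [annotate(v, locus, haplotype) for v in variants]
    return calls, filter_reportable(calls)


def classify_zygosity(
    sample_id: str,
    group: str,
    hap1_reportable: list[VariantCall] | tuple[str, ...],
    hap2_reportable: list[VariantCall] | tuple[str, ...],
) -> ZygosityCall:
    """Zygosity from the two haplotypes' reportable variant sets."""

    def names(x):
        return tuple(sorted(c.hgvs_c if isinstance(c, VariantCall) else c for c in x))

    s1, s2 = names(hap1_reportable), names(hap2_reportable)
    if s1 and s2:
        z = "homozygous" if set(s1) == set(s2) else "compound_heterozygous"
    elif s1 or s2:
        z = "single_heterozygous"
    else:
        z = "none"
    return ZygosityCall(sample_id, group, z, s1, s2)


@dataclass
class SpectrumTable:
    """Cohort variant spectrum over type I and type II haplotypes.

    ``per_variant`` counts every distinct reportable variant;
    ``signatures`` mirrors the study's presentation: one row per distinct
    haplotype variant signature with the promoter SNV excluded.
    Frequencies are recomputed from counts at access time.
    """

    n_hap_i: int
    n_hap_ii: int
    variant_counts: Counter
    signature_counts: Counter
    regions: dict

    @property
    def per_variant(self) -> pd.DataFrame:
        rows = []
        for (name, grp), n in sorted(self.variant_counts.items()):
            rows.append((name, grp, n))
        df = pd.DataFrame(rows, columns=["variant", "group", "count"])
        piv = df.pivot_table(index="variant", columns="group", values="count",
                             aggfunc="sum", fill_value=0)
        piv = piv.reindex(columns=["I", "II"], fill_value=0).reset_index()
        piv.columns = ["variant", "count_I", "count_II"]
        piv["region"] = piv["variant"].map(self.regions)
        piv["freq_I"] = piv["count_I"] / self.n_hap_i
        piv["freq_II"] = piv["count_II"] / self.n_hap_ii
        return piv[["variant", "region", "count_I", "freq_I", "count_II", "freq_II"]]

    @property
    def signatures(self) -> pd.DataFrame:
        rows = []
        for (sig, grp), n in sorted(self.signature_counts.items()):
            rows.append(("; ".join(sig), grp, n))
        df = pd.DataFrame(rows, columns=["signature", "group", "count"])
        piv = df.pivot_table(index="signature", columns="group", values="count",
                             aggfunc="sum", fill_value=0)
        piv = piv.reindex(columns=["I", "II"], fill_value=0).reset_index()
        piv.columns = ["signature", "count_I", "count_II"]
        piv["freq_I"] = piv["count_I"] / self.n_hap_i
        piv["freq_II"] = piv["count_II"] / self.n_hap_ii
        return piv

    def variant_frequency(self, name: str, group: str) -> float:
        n = self.variant_counts.get((name, group), 0)
        return n / (self.n_hap_i if group == "I" else self.n_hap_ii)


def tabulate_spectrum(
    hap_calls: list[tuple[str, str, tuple[str, ...]]],
    locus: LocusModel,
    promoter: str = PROMOTER_VARIANT,
) -> SpectrumTable:
    """Build the spectrum from (sample_id, group, reportable names) per haplotype."""
    from .variants import parse_hgvs

    variant_counts: Counter = Counter()
    signature_counts: Counter = Counter()
    regions: dict = {}
    n_i = n_ii = 0
    for _sid, grp, names in hap_calls:
        if grp == "I":
            n_i += 1
        elif grp == "II":
            n_ii += 1
        else:
            continue
        for name in names:
            variant_counts[(name, grp)] += 1
            if name not in regions:
                v = parse_hgvs(name, locus.transcript, locus.reference)
                regions[name] = locus.transcript.region_label(
                    normalize_variant(v, locus.reference).pos
                )
        sig = tuple(sorted(n for n in names if n != promoter))
        if sig:
            signature_counts[(sig, grp)] += 1
    return SpectrumTable(
        n_hap_i=n_i,
        n_hap_ii=n_ii,
        variant_counts=variant_counts,
        signature_counts=signature_counts,
        regions=regions,
    )
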