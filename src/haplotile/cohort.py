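"""Diploid samples: the 43-sample deficiency cohort and the donor screen cohort.

The deficiency cohort encodes the study's per-haplotype genotypes: 14 type I
samples (all carrying candidate loss-of-function genotypes on both
haplotypes, one of them homozygous) and 29 type II samples (26 of whose 58
haplotypes carry a reportable variant).  The recurrent structural variant —
a 19,971-bp deletion-insertion removing exons 2-3 and the translation start
— appears on one haplotype of three type I samples and one type II sample.

Variant names are canonical c.-space HGVS against the synthetic transcript.
The large delins is written with the linear upstream convention; its right
end renders as c.120+3885, consistent with a 19,971-base deletion (the
source nomenclature prints the interval as ...120+3887, which counts two
additional junction-ambiguous positions; see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .simulate import LocusModel, PHASING_SNV_POSITIONS, SV_FIRST_DELETED, SV_LAST_DELETED
from .variants import Variant, apply_variants, parse_hgvs

__all__ = [
    "DiploidSample",
    "Cohort",
    "SV_HGVS_C",
    "TABLE2_GENOTYPES",
    "make_table2_cohort",
    "make_cohort",
]

SV_HGVS_C = "c.1-15966_c.120+3885delinsCCAATGCTAAGGTTGA"

# (sample_id, deficiency type, haplotype-1 variants, haplotype-2 variants)
TABLE2_GENOTYPES: tuple[tuple[str, str, tuple[str, ...], tuple[str, ...]], ...] = (
    ("I-01", "I", ("c.-132A>C",), ("c.430-1G>C", "c.-132A>C")),
    ("I-02", "I", ("c.-132A>C",), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-03", "I", ("c.-132A>C",), ("c.1229T>C", "c.-132A>C")),
    ("I-04", "I", ("c.332_333delCA", "c.-132A>C"), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-05", "I", ("c.332_333delCA", "c.-132A>C"), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-06", "I", ("c.332_333delCA", "c.-132A>C"), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-07", "I", ("c.380C>T",), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-08", "I", ("c.430-2A>G",), ("c.609+7A>G", "c.-132A>C")),
    ("I-09", "I", ("c.1228_1239delATTGTGCCTATT",), ("c.1156C>T",)),
    ("I-10", "I", ("c.1228_1239delATTGTGCCTATT",), ("c.1156C>T", "c.1409C>T")),
    ("I-11", "I", ("c.1228_1239delATTGTGCCTATT",), ("c.1228_1239delATTGTGCCTATT",)),
    ("I-12", "I", (SV_HGVS_C,), ("c.1006+2T>G",)),
    ("I-13", "I", (SV_HGVS_C,), ("c.1156C>T", "c.1409C>T")),
    ("I-14", "I", (SV_HGVS_C,), ("c.1163A>T",)),
    ("II-01", "II", ("c.-132A>C",), ()),
    ("II-02", "II", ("c.-132A>C",), ()),
    ("II-03", "II", ("c.220C>T", "c.-132A>C"), ("c.-132A>C",)),
    ("II-04", "II", ("c.275C>T",), ()),
    ("II-05", "II", ("c.332_333delCA",), ()),
    ("II-06", "II", ("c.332_333delCA", "c.-132A>C"), ()),
    ("II-07", "II", ("c.332_333delCA", "c.-132A>C"), ()),
    ("II-08", "II", ("c.332_333delCA", "c.-132A>C"), ()),
    ("II-09", "II", ("c.332_333delCA", "c.-132A>C"), ()),
    ("II-10", "II", ("c.332_333delCA", "c.-132A>C"), ()),
    ("II-11", "II", ("c.429+3insG",), ()),
    ("II-12", "II", ("c.847G>A",), ()),
    ("II-13", "II", ("c.1156C>T",), ()),
    ("II-14", "II", ("c.1156C>T",), ()),
    ("II-15", "II", ("c.1156C>T", "c.1409C>T"), ()),
    ("II-16", "II", ("c.1228_1239delATTGTGCCTATT",), ()),
    ("II-17", "II", ("c.1228_1239delATTGTGCCTATT",), ()),
    ("II-18", "II", ("c.1228_1239delATTGTGCCTATT",), ("c.-132A>C",)),
    ("II-19", "II", ("c.1228_1239delATTGTGCCTATT",), ("c.609+7A>G", "c.-132A>C")),
    ("II-20", "II", ("c.1228_1239delATTGTGCCTATT", "c.-132A>C"), ()),
    ("II-21", "II", ("c.1340_1343dupTCTT",), ()),
    ("II-22", "II", (SV_HGVS_C,), ("c.681C>A",)),
    ("II-23", "II", (), ()),
    ("II-24", "II", (), ()),
    ("II-25", "II", (), ()),
    ("II-26", "II", (), ()),
    ("II-27", "II", (), ()),
    ("II-28", "II", (), ()),
    ("II-29", "II", (), ()),
)


@dataclass(frozen=True)
class DiploidSample:
    """Two haplotype sequences derived from truth variant lists."""

    sample_id: str
    group: str  # "I" | "II" | "donor"
    hap1_variants: tuple[str, ...]  # canonical c. HGVS, reportable truth
    hap2_variants: tuple[str, ...]
    hap1_extra: tuple[str, ...]  # benign marker SNVs (non-reportable truth)
    hap2_extra: tuple[str, ...]
    hap1_seq: str
    hap2_seq: str

    @property
    def is_sv_carrier(self) -> bool:
        return SV_HGVS_C in self.hap1_variants + self.hap2_variants

    @property
    def sv_haplotype(self) -> str | None:
        if SV_HGVS_C in self.hap1_variants:
            return "H1"
        if SV_HGVS_C in self.hap2_variants:
            return "H2"
        return None

    def hap_seq(self, hap: str) -> str:
        return self.hap1_seq if hap == "H1" else self.hap2_seq

    def truth_variant_names(self, hap: str) -> tuple[str, ...]:
        return self.hap1_variants if hap == "H1" else self.hap2_variants


def _parse_all(locus: LocusModel, names: tuple[str, ...]) -> list[Variant]:
    return [parse_hgvs(n, locus.transcript, locus.reference) for n in names]


@lru_cache(maxsize=None)
def _hap_sequence_cached(locus_seed: int, names: tuple[str, ...]) -> str:
    # cache keyed by the locus seed + variant list; identical genotypes in a
    # large cohort share one sequence object
    locus = _locus_by_seed(locus_seed)
    seq, _ = apply_variants(locus.reference, _parse_all(locus, names))
    return seq


_LOCUS_REGISTRY: dict[int, LocusModel] = {}


def _locus_by_seed(seed: int) -> LocusModel:
    return _LOCUS_REGISTRY[seed]


def _register(locus: LocusModel) -> None:
    _LOCUS_REGISTRY.setdefault(locus.seed, locus)


@lru_cache(maxsize=None)
def _canonical_names(locus_seed: int, names: tuple[str, ...]) -> tuple[str, ...]:
    from .variants import format_hgvs_c, normalize_variant

    locus = _locus_by_seed(locus_seed)
    return tuple(
        format_hgvs_c(
            normalize_variant(parse_hgvs(n, locus.transcript, locus.reference),
                              locus.reference),
            locus.transcript,
            locus.reference,
        )
        for n in names
    )


def build_sample(
    locus: LocusModel,
    sample_id: str,
    group: str,
    hap1: tuple[str, ...],
    hap2: tuple[str, ...],
    hap1_extra: tuple[str, ...] = (),
    hap2_extra: tuple[str, ...] = (),
) -> DiploidSample:
    """Truth variant names are canonicalized (3'-shifted, standard form) so
    they compare equal to pipeline calls; sequences derive from the same
    parsed variants."""
    _register(locus)
    hap1, hap2 = tuple(hap1), tuple(hap2)
    hap1_c = _canonical_names(locus.seed, hap1)
    hap2_c = _canonical_names(locus.seed, hap2)
    return _build_sample_canonical(
        locus, sample_id, group, hap1_c, hap2_c, tuple(hap1_extra), tuple(hap2_extra)
    )


def _build_sample_canonical(
    locus, sample_id, group, hap1, hap2, hap1_extra, hap2_extra
) -> DiploidSample:
    return DiploidSample(
        sample_id=sample_id,
        group=group,
        hap1_variants=tuple(hap1),
        hap2_variants=tuple(hap2),
        hap1_extra=tuple(hap1_extra),
        hap2_extra=tuple(hap2_extra),
        hap1_seq=_hap_sequence_cached(locus.seed, tuple(hap1) + tuple(hap1_extra)),
        hap2_seq=_hap_sequence_cached(locus.seed, tuple(hap2) + tuple(hap2_extra)),
    )


def _marker_names(locus: LocusModel, positions=PHASING_SNV_POSITIONS) -> tuple[str, ...]:
    from .variants import format_hgvs_c

    return tuple(
        format_hgvs_c(locus.phasing_snv(p), locus.transcript, locus.reference)
        for p in positions
    )


def make_table2_cohort(locus: LocusModel, phasing_snvs: bool = False) -> list[DiploidSample]:
    """The 43-sample deficiency cohort (28 type I + 58 type II haplotypes).

    With ``phasing_snvs=True`` every sample additionally carries the panel of
    benign deep-intronic marker SNVs on haplotype 2, guaranteeing at least
    one heterozygous site per amplicon and per overlap; markers are
    non-reportable so truth genotypes are unchanged.
    """
    markers = _marker_names(locus) if phasing_snvs else ()
    return [
        build_sample(locus, sid, grp, h1, h2, hap2_extra=markers)
        for sid, grp, h1, h2 in TABLE2_GENOTYPES
    ]


@dataclass(frozen=True)
class Cohort:
    donors: tuple[DiploidSample, ...]
    carrier_ids: frozenset[str]

    @property
    def n(self) -> int:
        return len(self.donors)


# population allele frequencies of benign background variants available to
# donor haplotypes (the promoter SNV plus two deep-intronic markers)
_BACKGROUND_AF: tuple[tuple[str, float], ...] = ()


def _background_catalog(locus: LocusModel) -> tuple[tuple[str, float], ...]:
    markers = _marker_names(locus, (30_000, 70_000))
    return (
        ("c.-132A>C", 0.08),
        (markers[0], 0.10),
        (markers[1], 0.10),
    )


def make_cohort(
    locus: LocusModel,
    n: int = 600,
    n_carriers: int = 3,
    seed: int | np.random.Generator = 0,
    background_snvs: bool = True,
) -> Cohort:
    """A donor cohort with exactly `n_carriers` heterozygous SV carriers.

    Non-carrier haplotypes optionally draw common benign SNVs so the screen
    runs against realistic background diversity.
    """
    if n_carriers > n:
        raise ValueError("n_carriers cannot exceed cohort size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        np.random.SeedSequence([locus.seed, 11, int(seed)])
    )
    carrier_idx = set(map(int, rng.choice(n, size=n_carriers, replace=False)))
    catalog = _background_catalog(locus) if background_snvs else ()
    in_deletion = {
        name
        for name, _ in catalog
        if SV_FIRST_DELETED
        <= parse_hgvs(name, locus.transcript, locus.reference).pos
        <= SV_LAST_DELETED
    }
    donors = []
    for i in range(n):
        haps: list[tuple[str, ...]] = []
        sv_hap = int(rng.integers(0, 2)) if i in carrier_idx else -1
        for h in range(2):
            vs: list[str] = [SV_HGVS_C] if h == sv_hap else []
            for name, af in catalog:
                if rng.random() < af and not (h == sv_hap and name in in_deletion):
                    vs.append(name)
            haps.append(tuple(vs))
        donors.append(
            build_sample(locus, f"D{i + 1:04d}", "donor", haps[0], haps[1])
        )
    return Cohort(
        donors=tuple(donors),
        carrier_ids=frozenset(d.sample_id for j, d in enumerate(donors) if j in carrier_idx),
    )
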