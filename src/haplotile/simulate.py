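"""Synthetic locus, amplicon panel and long-read simulation.

The generator emulates the study system: a ~77 kb blood-group gene with 15
exons (12 coding, translation start in exon 3), tiled by four long-range
PCR amplicons of 20.6 / 22 / 20.6 / 23 kb with >= 3 kb overlaps, plus a
gap-PCR assay whose deletion-flanking primers sit 571/261 bp from the
junction of a cryptic 19,971-bp deletion-insertion (16-bp insert) spanning
intron 1 to intron 3.  Background sequence is random under a fixed seed;
every functional feature (primer sites, exon boundaries, splice dinucleotides,
reference alleles of the cohort's variants, the SV junction context) is
planted deterministically so that coordinates and product sizes reproduce
the assay geometry exactly.

Read simulation uses a flat per-base error model (substitution / insertion /
deletion rates) with Gaussian read lengths: a nanopore-like profile for
amplicon reads and a HiFi-like profile for whole-locus reads.  Every read
carries its truth provenance (sample, haplotype, amplicon, template
interval, strand).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus import LocusReference, TranscriptModel
from .pcr import PCRProduct, PrimerPair, find_primer_sites, revcomp
from .variants import Variant

__all__ = [
    "ErrorModel",
    "AMPLICON_ERROR_MODEL",
    "WGS_ERROR_MODEL",
    "Amplicon",
    "AmpliconPanel",
    "GapAssay",
    "LocusModel",
    "SimulatedRead",
    "build_reference_locus",
    "simulate_reads",
    "simulate_wgs_reads",
    "LOCUS_LENGTH",
    "SV_INSERT",
    "SV_FIRST_DELETED",
    "SV_LAST_DELETED",
    "PHASING_SNV_POSITIONS",
]

# ---------------------------------------------------------------------------
# fixed locus layout (1-based inclusive coordinates)

LOCUS_LENGTH = 77_000

EXONS: tuple[tuple[int, int], ...] = (
    (1_500, 1_700),    # exon 1, noncoding
    (38_000, 38_150),  # exon 2, noncoding
    (40_816, 41_085),  # exon 3: 150 bp 5'UTR + c.1..120
    (54_000, 54_210),  # exon 4: c.121..331
    (55_500, 55_597),  # exon 5: c.332..429
    (57_000, 57_179),  # exon 6: c.430..609
    (58_500, 58_590),  # exon 7: c.610..700
    (60_000, 60_064),  # exon 8: c.701..765
    (61_500, 61_554),  # exon 9: c.766..820
    (63_000, 63_185),  # exon 10: c.821..1006
    (65_000, 65_113),  # exon 11: c.1007..1120
    (67_000, 67_093),  # exon 12: c.1121..1214
    (69_000, 69_115),  # exon 13: c.1215..1330
    (71_000, 71_235),  # exon 14: c.1331..1416 + 150 bp 3'UTR
    (73_000, 73_400),  # exon 15, noncoding 3'UTR
)
CDS_START = 40_966  # c.1
CDS_END = 71_085    # c.1416

# structural variant truth: 19,971 deleted bases, 16 inserted
SV_INSERT = "CCAATGCTAAGGTTGA"
SV_FIRST_DELETED = CDS_START - 15_966          # 25,000: in intron 1
SV_LAST_DELETED = SV_FIRST_DELETED + 19_970    # 44,970: 3,885 bp into intron 3

# amplicon tiling (product coordinates: forward-primer 5' end .. reverse-primer 5' end)
_AMPLICON_COORDS = ((300, 20_899), (17_900, 39_899), (36_900, 57_499), (53_500, 76_499))

# primer panel (sequences as synthesized, 5'->3')
LR_PRIMERS = (
    PrimerPair("amplicon1", "CTCCCTCACCACCTATCCCTATAAGCT", "CTGCCACTGCTTCATCAACCAACTTTA"),
    PrimerPair("amplicon2", "CAAAGTGGCTACGGCGATTGTAAGGATC", "ACAGTAGTGTCACCTCCCGTCATCTGG"),
    PrimerPair("amplicon3", "TCCAAATTCAGACTCGGATTCCATTCAT", "ACCTTACCATACACTTGCAGCAGAAAT"),
    PrimerPair("amplicon4", "GGCTTAGACAGTAAATGCTATGAACCAAG", "CACCGTCTTACACTTTGCTACTTCTTACA"),
)
GAP_DELETION_PAIR = PrimerPair("gap_deletion", "GTGTCAAACTGTCATCGGGGTG", "GACCCTTTTCCACAGTGCTTTG")
GAP_CONTROL_PAIR = PrimerPair("gap_control", "CAGAGAGATGTGGAGGGGAGTT", "TCTTGCCCCTTCCTCCCTTTA")

# gap-assay geometry: flanks measured on the deletion allele from the junction
GAP_5F_START = SV_FIRST_DELETED - 555   # 555 ref bases + 16-bp insert = 571 to junction
GAP_5R_END = SV_LAST_DELETED + 261      # outer end 261 bases past the deletion
GAP_CONTROL_START = 59_000              # intron 7
GAP_CONTROL_END = GAP_CONTROL_START + 332  # 333-bp control product

# benign heterozygous marker SNVs emulating natural diploid diversity
# (~1 het site / 2.5 kb): every long read then covers at least one
# informative site and every overlap is phaseable.  All positions are deep
# intronic or outside the transcript (>100 bp from any exon boundary and
# clear of all primer sites), hence never reportable.
PHASING_SNV_POSITIONS = (
    3_000, 6_000, 9_000, 12_000, 15_000, 18_200, 21_500, 24_000, 27_000,
    30_000, 33_000, 35_500, 37_300, 39_000, 40_300, 42_500, 44_000, 46_500,
    49_000, 51_500, 53_700, 55_000, 56_300, 58_000, 59_600, 60_700, 62_300,
    64_000, 66_000, 68_000, 70_000, 72_000, 74_500, 75_800,
)
_TRANSVERSION = {"A": "C", "C": "A", "G": "T", "T": "G"}


@dataclass(frozen=True)
class ErrorModel:
    """Flat per-base read error model; rates are probabilities per base."""

    substitution_rate: float
    insertion_rate: float
    deletion_rate: float
    read_length_mean: float
    read_length_sd: float

    def __post_init__(self) -> None:
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if not 0.0 <= r <= 0.15:
                raise ValueError("error rates must lie in [0, 0.15]")


AMPLICON_ERROR_MODEL = ErrorModel(0.02, 0.015, 0.025, 8_000, 2_000)
WGS_ERROR_MODEL = ErrorModel(0.002, 0.002, 0.002, 12_000, 3_000)
# long reads after depth-based error correction (the polishing step the
# pipeline applies before base-exact breakpoint comparison)
CORRECTED_ERROR_MODEL = ErrorModel(0.002, 0.002, 0.002, 8_000, 2_000)


@dataclass(frozen=True)
class Amplicon:
    name: str
    pair: PrimerPair
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class AmpliconPanel:
    amplicons: tuple[Amplicon, ...]

    def __post_init__(self) -> None:
        if len(self.amplicons) != 4:
            raise ValueError("the tiling panel has four amplicons")
        for a in self.amplicons:
            if not 20_000 <= a.length <= 23_500:
                raise ValueError(f"{a.name} length {a.length} outside 20-23.5 kb")
        for ov in self.overlaps:
            if ov < 3_000:
                raise ValueError("adjacent amplicons must overlap by >= 3 kb")

    @property
    def overlaps(self) -> tuple[int, ...]:
        return tuple(
            self.amplicons[i].end - self.amplicons[i + 1].start + 1
            for i in range(len(self.amplicons) - 1)
        )

    def overlap_interval(self, junction: int) -> tuple[int, int]:
        """1-based locus interval shared by amplicons junction and junction+1 (0-based)."""
        return (self.amplicons[junction + 1].start, self.amplicons[junction].end)

    def __iter__(self):
        return iter(self.amplicons)

    def __len__(self) -> int:
        return len(self.amplicons)


@dataclass(frozen=True)
class GapAssay:
    """Multiplex gap-PCR: deletion-flanking pair + internal control pair."""

    deletion_pair: PrimerPair
    control_pair: PrimerPair
    max_product: int = 2_000  # short-extension cycling cannot make LR products
    expected_deletion_band: int = 832
    expected_control_band: int = 333


@dataclass(frozen=True)
class LocusModel:
    """The full synthetic study system: reference + transcript + assays."""

    reference: LocusReference
    transcript: TranscriptModel
    panel: AmpliconPanel
    gap_assay: GapAssay
    sv_truth: Variant
    lr_max_product: int = 25_000  # long-extension LR-PCR ceiling
    seed: int = 0

    def phasing_snv(self, pos: int) -> Variant:
        """The benign marker SNV planted at a clustering/phasing position."""
        b = self.reference.base(pos)
        return Variant(pos=pos, ref=b, alt=_TRANSVERSION[b])


def _transcript() -> TranscriptModel:
    return TranscriptModel(exons=EXONS, cds_start=CDS_START, cds_end=CDS_END)


def _planted_bases(t: TranscriptModel) -> dict[int, str]:
    """All deterministic base plantings: (1-based pos) -> base."""
    from .locus import c_to_g

    plants: dict[int, str] = {}

    def put(pos: int, seq: str) -> None:
        for i, b in enumerate(seq):
            plants[pos + i] = b

    # start and stop codons
    put(CDS_START, "ATG")
    put(CDS_END - 2, "TAA")
    # canonical splice dinucleotides for every intron
    for (s1, e1), (s2, _) in zip(EXONS, EXONS[1:]):
        put(e1 + 1, "GT")
        put(s2 - 2, "AG")

    # reference alleles of the cohort catalogue (contexts engineered so the
    # printed variant names are already 3'-canonical)
    cplants = {
        "c.-132": "A",
        "c.220": "C",
        "c.275": "C",
        "c.332": "C",
        "c.333": "A",
        "c.334": "T",   # blocks 3'-shifting of the CA deletion
        "c.380": "C",
        "c.429+3": "A",
        "c.429+4": "C",  # blocks 3'-shifting of the G insertion
        "c.609+7": "A",
        "c.681": "C",
        "c.847": "G",
        "c.1156": "C",
        "c.1163": "A",
        "c.1409": "C",
    }
    for cstr, b in cplants.items():
        plants[c_to_g(cstr, t)] = b
    # 13-base repeat context of the recurrent 12-bp deletion: the c.1227 and
    # c.1228_1239 descriptions are aliases; c.1240 breaks the repeat
    put(c_to_g("c.1227", t), "TATTGTGCCTATT" + "G")
    # duplication target TCTT with a shift-blocking base after it
    put(c_to_g("c.1340", t), "TCTT" + "A")
    # SV junction context: the deleted segment's first and last 16 bases
    # mismatch the insert base-for-base, so no alignment can absorb insert
    # bases into a flank as substitutions — the junction has a unique
    # parsimony placement and the truth delins is its own canonical form
    for j, b in enumerate(SV_INSERT):
        plants[SV_FIRST_DELETED + j] = _TRANSVERSION[b]
        plants[SV_LAST_DELETED - len(SV_INSERT) + 1 + j] = _TRANSVERSION[b]
    return plants


def _primer_plants() -> dict[int, str]:
    plants: dict[int, str] = {}

    def put(pos: int, seq: str) -> None:
        for i, b in enumerate(seq):
            plants[pos + i] = b

    for pair, (s, e) in zip(LR_PRIMERS, _AMPLICON_COORDS):
        put(s, pair.forward)
        put(e - len(pair.reverse) + 1, revcomp(pair.reverse))
    put(GAP_5F_START, GAP_DELETION_PAIR.forward)
    put(GAP_5R_END - len(GAP_DELETION_PAIR.reverse) + 1, revcomp(GAP_DELETION_PAIR.reverse))
    put(GAP_CONTROL_START, GAP_CONTROL_PAIR.forward)
    put(GAP_CONTROL_END - len(GAP_CONTROL_PAIR.reverse) + 1, revcomp(GAP_CONTROL_PAIR.reverse))
    return plants


_ALL_PRIMERS = tuple(LR_PRIMERS) + (GAP_DELETION_PAIR, GAP_CONTROL_PAIR)


def _primer_sites_unique(seq: str) -> bool:
    """Every primer must have exactly one annealing-tolerant site per strand."""
    for pair in _ALL_PRIMERS:
        if len(find_primer_sites(seq, pair.forward)) != 1:
            return False
        if len(find_primer_sites(seq, revcomp(pair.reverse))) != 1:
            return False
        # no spurious convergent sites on the opposite orientation
        if find_primer_sites(seq, revcomp(pair.forward)):
            return False
        if find_primer_sites(seq, pair.reverse):
            return False
    return True


def build_reference_locus(seed: int = 0, max_retries: int = 10) -> LocusModel:
    """Generate the synthetic locus with all planted assay features.

    The random background is regenerated (bounded retries) in the unlikely
    event that it contains a spurious primer annealing site.
    """
    t = _transcript()
    plants = _planted_bases(t) | _primer_plants()
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 7, attempt]))
        arr = bases[rng.integers(0, 4, LOCUS_LENGTH)]
        for pos, b in plants.items():
            arr[pos - 1] = ord(b)
        seq = arr.tobytes().decode("ascii")
        if _primer_sites_unique(seq):
            break
    else:
        raise RuntimeError("could not build a locus free of spurious primer sites")

    reference = LocusReference(name="LOCUS77K", sequence=seq)
    panel = AmpliconPanel(
        amplicons=tuple(
            Amplicon(name=pair.name, pair=pair, start=s, end=e)
            for pair, (s, e) in zip(LR_PRIMERS, _AMPLICON_COORDS)
        )
    )
    sv_truth = Variant(
        pos=SV_FIRST_DELETED,
        ref=reference.slice(SV_FIRST_DELETED, SV_LAST_DELETED),
        alt=SV_INSERT,
    )
    gap = GapAssay(deletion_pair=GAP_DELETION_PAIR, control_pair=GAP_CONTROL_PAIR)
    return LocusModel(
        reference=reference,
        transcript=t,
        panel=panel,
        gap_assay=gap,
        sv_truth=sv_truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass(frozen=True)
class SimulatedRead:
    """A simulated long read with its truth provenance."""

    read_id: str
    sequence: str
    sample_id: str
    haplotype: str       # "H1" | "H2"
    amplicon: str        # amplicon name or "wgs"
    template_start: int  # 1-based on the template the read was drawn from
    template_end: int
    strand: str          # "+" | "-"

    @property
    def comment(self) -> str:
        return (
            f"sample={self.sample_id} hap={self.haplotype} amplicon={self.amplicon} "
            f"span={self.template_start}-{self.template_end} strand={self.strand}"
        )


_A2CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _A2CODE[_b] = _i
_CODE2A = np.frombuffer(b"ACGT", dtype=np.uint8)


def _mutate(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    """Apply flat substitution/insertion/deletion errors (vectorized)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _A2CODE[raw].astype(np.int64)
    n = len(codes)
    u = rng.random(n)
    is_sub = u < model.substitution_rate
    is_del = (u >= model.substitution_rate) & (
        u < model.substitution_rate + model.deletion_rate
    )
    has_ins = rng.random(n) < model.insertion_rate
    codes[is_sub] = (codes[is_sub] + rng.integers(1, 4, int(is_sub.sum()))) % 4
    slots = (~is_del).astype(np.int64) + has_ins
    total = int(slots.sum())
    out = np.empty(total, dtype=np.uint8)
    ends = np.cumsum(slots)
    starts = ends - slots
    kept = ~is_del
    out[starts[kept]] = _CODE2A[codes[kept]]
    ins_codes = rng.integers(0, 4, int(has_ins.sum()))
    out[ends[has_ins] - 1] = _CODE2A[ins_codes]
    return out.tobytes().decode("ascii")


def _sample_reads(
    template: str,
    depth: float,
    model: ErrorModel,
    rng: np.random.Generator,
    sample_id: str,
    haplotype: str,
    amplicon: str,
    id_prefix: str,
    end_anchored_fraction: float = 0.5,
) -> list[SimulatedRead]:
    """Reads from one template; a fraction start at a template end.

    PCR products are sequenced from molecule ends (adapter ligation), with
    the remainder modelling internal fragmentation, so product edges — the
    phasing-critical overlap zones — keep full coverage.
    """
    L = len(template)
    n_reads = max(1, round(depth * L / model.read_length_mean))
    reads = []
    for i in range(n_reads):
        length = int(rng.normal(model.read_length_mean, model.read_length_sd))
        length = int(np.clip(length, min(200, L), L))
        u = rng.random()
        if u < end_anchored_fraction / 2:
            start = 0
        elif u < end_anchored_fraction:
            start = L - length
        else:
            start = int(rng.integers(0, L - length + 1))
        frag = template[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        reads.append(
            SimulatedRead(
                read_id=f"{id_prefix}/{i:05d}",
                sequence=_mutate(frag, model, rng),
                sample_id=sample_id,
                haplotype=haplotype,
                amplicon=amplicon,
                template_start=start + 1,
                template_end=start + length,
                strand=strand,
            )
        )
    return reads


def simulate_reads(
    product: PCRProduct | str,
    depth: float,
    error_model: ErrorModel = AMPLICON_ERROR_MODEL,
    rng: np.random.Generator | int | None = 0,
    sample_id: str = "sample",
    haplotype: str = "H1",
    amplicon: str | None = None,
) -> list[SimulatedRead]:
    """Simulate reads from one amplicon product (or raw template string)."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    template = product.sequence if isinstance(product, PCRProduct) else product
    name = amplicon or (product.pair.name if isinstance(product, PCRProduct) else "template")
    return _sample_reads(
        template, depth, error_model, rng,
        sample_id=sample_id, haplotype=haplotype, amplicon=name,
        id_prefix=f"{sample_id}.{haplotype}.{name}",
    )


def simulate_wgs_reads(
    hap1_seq: str,
    hap2_seq: str,
    depth: float,
    error_model: ErrorModel = WGS_ERROR_MODEL,
    rng: np.random.Generator | int | None = 0,
    sample_id: str = "sample",
) -> list[SimulatedRead]:
    """Whole-locus long reads drawn from both haplotypes with equal probability.

    `depth` is total diploid coverage (each haplotype contributes ~depth/2).
    """
    if depth < 10:
        raise ValueError("whole-locus simulation expects depth >= 10")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean_len = (len(hap1_seq) + len(hap2_seq)) / 2
    n_reads = max(1, round(depth * mean_len / error_model.read_length_mean))
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        hap = "H1" if rng.random() < 0.5 else "H2"
        template = hap1_seq if hap == "H1" else hap2_seq
        L = len(template)
        length = int(np.clip(int(rng.normal(error_model.read_length_mean,
                                            error_model.read_length_sd)), 1_000, L))
        start = int(rng.integers(0, L - length + 1))
        frag = template[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        reads.append(
            SimulatedRead(
                read_id=f"{sample_id}.wgs/{i:05d}",
                sequence=_mutate(frag, error_model, rng),
                sample_id=sample_id,
                haplotype=hap,
                amplicon="wgs",
                template_start=start + 1,
                template_end=start + length,
                strand=strand,
            )
        )
    return reads
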