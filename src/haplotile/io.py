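"""File formats: FASTA/FASTQ via Biopython, BED, VCF 4.2, bedgraph, TSV,
optional SAM export via pysam, and a checksummed run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import LocusModel, SimulatedRead
from .variants import Variant

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_fastq",
    "read_fastq",
    "write_bed",
    "write_locus_bed",
    "write_vcf",
    "write_bedgraph",
    "write_tsv",
    "write_sam",
    "write_manifest",
]


def write_fasta(records: list[tuple[str, str]] | dict, path) -> Path:
    path = Path(path)
    items = records.items() if isinstance(records, dict) else records
    seqs = [
        SeqRecord(Seq(seq), id=name.split()[0],
                  description=name[len(name.split()[0]):].strip())
        for name, seq in items
    ]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")
    return path


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: list[SimulatedRead], path, quality: int = 20) -> Path:
    """FASTQ with a flat quality profile; truth provenance in the comment."""
    path = Path(path)
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id} {r.comment}\n{r.sequence}\n+\n")
            fh.write(chr(33 + quality) * len(r.sequence) + "\n")
    return path


def read_fastq(path) -> list[SimulatedRead]:
    """Read FASTQ written by :func:`write_fastq`, recovering provenance."""
    out = []
    with open(path) as fh:
        while True:
            header = fh.readline().strip()
            if not header:
                break
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            name, _, comment = header[1:].partition(" ")
            meta = dict(
                kv.split("=", 1) for kv in comment.split() if "=" in kv
            )
            span = meta.get("span", "0-0").split("-")
            out.append(
                SimulatedRead(
                    read_id=name,
                    sequence=seq,
                    sample_id=meta.get("sample", "?"),
                    haplotype=meta.get("hap", "?"),
                    amplicon=meta.get("amplicon", "?"),
                    template_start=int(span[0]),
                    template_end=int(span[1]),
                    strand=meta.get("strand", "+"),
                )
            )
    return out


def write_bed(intervals: list[tuple], path) -> Path:
    """BED from (chrom, start_1based, end_1based, name) tuples."""
    path = Path(path)
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
    return path


def write_locus_bed(locus: LocusModel, path) -> Path:
    """Exons, amplicons and the truth deletion-insertion as one BED track."""
    rows = []
    chrom = locus.reference.name
    for i, (s, e) in enumerate(locus.transcript.exons):
        rows.append((chrom, s, e, f"exon_{i + 1}"))
    for amp in locus.panel:
        rows.append((chrom, amp.start, amp.end, amp.name))
    sv = locus.sv_truth
    rows.append((chrom, sv.pos, sv.end, f"truth_sv_delins_{len(sv.alt)}bp_insert"))
    return write_bed(rows, path)


_VCF_HEADER = """##fileformat=VCFv4.2
##source=haplotile
##contig=<ID={chrom},length={length}>
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Net length change">
##INFO=<ID=INSLEN,Number=1,Type=Integer,Description="Inserted bases">
##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">
##INFO=<ID=HOMLEN,Number=1,Type=Integer,Description="Junction microhomology length">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(
    calls: list[tuple[Variant, str]] | list[tuple[Variant, str, dict]],
    locus: LocusModel,
    path,
    sample: str = "sample",
    phase_set: int = 1,
) -> Path:
    """Phased VCF with explicit REF/ALT (no symbolic alleles).

    `calls` holds (variant, genotype) or (variant, genotype, info) tuples;
    genotype strings are phased ("1|0" etc.).  An anchor base is prepended
    for indels, per VCF convention.
    """
    path = Path(path)
    ref = locus.reference
    lines = [
        _VCF_HEADER.format(chrom=ref.name, length=ref.length, sample=sample)
    ]
    rows = []
    for item in calls:
        v, gt = item[0], item[1]
        info_extra = item[2] if len(item) > 2 else {}
        if v.ref and v.alt and len(v.ref) == 1 and len(v.alt) == 1:
            pos, r, a = v.pos, v.ref, v.alt
        elif v.ref == "":  # insertion after v.pos
            pos = v.pos
            anchor = ref.base(pos)
            r, a = anchor, anchor + v.alt
        else:  # deletion / delins: left-anchor
            pos = v.pos - 1 if v.pos > 1 else v.pos
            anchor = ref.base(pos) if v.pos > 1 else ""
            r = anchor + v.ref
            a = anchor + v.alt if (anchor + v.alt) else ref.base(pos)
        info = {"SVLEN": len(v.alt) - len(v.ref)}
        info.update(info_extra)
        info_s = ";".join(f"{k}={val}" for k, val in info.items())
        rows.append((pos, r, a, info_s, gt))
    rows.sort()
    for pos, r, a, info_s, gt in rows:
        lines.append(
            f"{ref.name}\t{pos}\t.\t{r}\t{a}\t.\tPASS\t{info_s}\tGT:PS\t{gt}:{phase_set}\n"
        )
    Path(path).write_text("".join(lines))
    return path


def write_bedgraph(track, locus: LocusModel, path) -> Path:
    path = Path(path)
    chrom = locus.reference.name
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="depth_w{track.window}"\n')
        for w, d in enumerate(track.depth):
            start = w * track.window
            end = min(start + track.window, locus.reference.length)
            fh.write(f"{chrom}\t{start}\t{end}\t{d:.2f}\n")
    return path


def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_sam(alignments, locus: LocusModel, path) -> Path:
    """Export ReadAlignment records as a SAM file (via pysam)."""
    import pysam

    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": locus.reference.name, "LN": locus.reference.length}],
        "PG": [{"ID": "haplotile", "PN": "haplotile"}],
    }
    op_map = {"=": 7, "X": 8, "I": 1, "D": 2, "M": 0}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.query
            seg.reference_id = 0
            seg.reference_start = aln.locus_start - 1
            seg.flag = 16 if aln.strand == "-" else 0
            seg.mapping_quality = 60
            seg.cigartuples = [(op_map[op], n) for n, op in aln.cigar]
            out.write(seg)
    return path


def write_manifest(outdir, config: dict | None = None) -> Path:
    """JSON manifest listing every output file with its sha256 checksum."""
    outdir = Path(outdir)
    files = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            files[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    manifest = {"files": files}
    if config is not None:
        manifest["config"] = config
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
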