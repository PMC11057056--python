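"""File-format helpers: FASTA via Biopython, SAM via pysam, BED and
block-TSV for alignment records, and TSV tables via pandas.

The block-TSV alignment format is a 6-column plain-text record:
``read_id  contig  block_starts  block_ends  mapq  n_blocks`` with
comma-separated 0-based half-open block coordinates — a grep-able stand-in
for BAM at toy scale.
"""

from __future__ import annotations

import os
from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import AlignmentRecord, GenomicInterval


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# --- BED ------------------------------------------------------------------


def write_bed(intervals: list[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.feature_id or "."
            strand = iv.strand or "."
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{strand}\n")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            out.append(GenomicInterval(contig, start, end, strand=strand, feature_id=name))
    return out


# --- alignment records: block TSV and SAM ---------------------------------

_BLOCK_TSV_HEADER = "read_id\tcontig\tblock_starts\tblock_ends\tmapq\tn_blocks\n"


def write_block_tsv(records: list[AlignmentRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(_BLOCK_TSV_HEADER)
        for r in records:
            starts = ",".join(str(b.start) for b in r.blocks)
            ends = ",".join(str(b.end) for b in r.blocks)
            fh.write(f"{r.read_id}\t{r.contig}\t{starts}\t{ends}\t{r.mapq}\t{len(r.blocks)}\n")


def read_block_tsv(path: str | os.PathLike) -> list[AlignmentRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id"):
            raise ValueError(f"{path}: not a block-TSV alignment file")
        for line in fh:
            read_id, contig, starts, ends, mapq, _ = line.rstrip("\n").split("\t")
            blocks = [
                GenomicInterval(contig, int(s), int(e))
                for s, e in zip(starts.split(","), ends.split(","))
            ]
            out.append(AlignmentRecord(read_id=read_id, contig=contig,
                                       blocks=blocks, mapq=int(mapq)))
    return out


def write_sam(
    records: list[AlignmentRecord],
    contig_lengths: dict[str, int],
    path: str | os.PathLike,
) -> None:
    """Plain-text SAM with M/N CIGARs built from the block structure; the
    query sequence is emitted as N-runs of the aligned length."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": n} for c, n in contig_lengths.items()],
    }
    tid = {c: i for i, c in enumerate(contig_lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for r in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.read_id
            a.reference_id = tid[r.contig]
            a.reference_start = r.blocks[0].start
            a.mapping_quality = r.mapq
            a.flag = 0
            cigar = []
            for prev, cur in zip([None] + r.blocks[:-1], r.blocks):
                if prev is not None and cur.start > prev.end:
                    cigar.append((3, cur.start - prev.end))  # N
                cigar.append((0, len(cur)))  # M
            a.cigartuples = cigar
            a.query_sequence = "N" * r.aligned_length()
            fh.write(a)


def read_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    """Read mapped records from SAM/BAM; 1-based SAM coordinates become
    0-based half-open blocks (pysam's native convention)."""
    out = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            contig = seg.reference_name
            blocks = [GenomicInterval(contig, s, e) for s, e in seg.get_blocks()]
            merged: list[GenomicInterval] = []
            for b in blocks:  # adjacent M-blocks split by I/D are rejoined
                if merged and b.start <= merged[-1].end:
                    merged[-1] = GenomicInterval(contig, merged[-1].start, max(merged[-1].end, b.end))
                else:
                    merged.append(b)
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name, contig=contig, blocks=merged,
                    mapq=seg.mapping_quality,
                )
            )
    return out


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
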