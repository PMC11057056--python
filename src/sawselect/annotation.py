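"""Gene-content reconciliation on intervals and read alignments: MAPQ-filtered
per-base coverage, low-coverage region extraction, overlap-exclusive interval
intersection, and ortholog-id-based redundancy removal.

Coordinates are 0-based half-open throughout; SAM input (1-based) is
converted on read.  Overlap means >= 1 shared base and is strand-blind,
matching unstranded library preparation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_MIN_MAPQ = 10
DEFAULT_COVERAGE_THRESHOLD = 5


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int
    end: int
    strand: str | None = None
    feature_id: str | None = None

    def __post_init__(self) -> None:
        if not self.contig:
            raise ValueError("contig must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class AlignmentRecord:
    """A read-to-reference alignment: ordered, non-overlapping blocks on one
    contig; gaps between consecutive blocks are introns/junctions."""

    read_id: str
    contig: str
    blocks: list[GenomicInterval]
    mapq: int = 60

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("record must have at least one block")
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        for b in self.blocks:
            if b.contig != self.contig:
                raise ValueError("all blocks must be on the record's contig")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if a.end > b.start:
                raise ValueError("blocks must be sorted and non-overlapping")

    def gaps(self) -> list[tuple[int, int]]:
        """Half-open (end-of-block, start-of-next-block) spans — the introns."""
        return [
            (a.end, b.start)
            for a, b in zip(self.blocks, self.blocks[1:])
            if b.start > a.end
        ]

    def aligned_length(self) -> int:
        return sum(len(b) for b in self.blocks)


def compute_coverage(
    records: list[AlignmentRecord],
    contig_lengths: dict[str, int],
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> dict[str, np.ndarray]:
    """Per-base read depth per contig; records below ``min_mapq`` are
    excluded entirely."""
    diff = {c: np.zeros(n + 1, dtype=np.int64) for c, n in contig_lengths.items()}
    for rec in records:
        if rec.mapq < min_mapq:
            continue
        if rec.contig not in diff:
            raise KeyError(f"record {rec.read_id} on unknown contig {rec.contig!r}")
        n = contig_lengths[rec.contig]
        for b in rec.blocks:
            if b.end > n:
                raise ValueError(
                    f"record {rec.read_id}: block [{b.start}, {b.end}) beyond "
                    f"contig {rec.contig} length {n}"
                )
            diff[rec.contig][b.start] += 1
            diff[rec.contig][b.end] -= 1
    return {c: d[:-1].cumsum() for c, d in diff.items()}


def low_coverage_regions(
    coverage: np.ndarray,
    threshold: int = DEFAULT_COVERAGE_THRESHOLD,
    contig: str = "contig1",
) -> list[GenomicInterval]:
    """Maximal runs of bases with depth strictly below ``threshold``."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    low = np.asarray(coverage) < threshold
    if not low.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], low, [False])).astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [GenomicInterval(contig, int(s), int(e)) for s, e in zip(starts, ends)]


def intersect_exclusive(
    candidates: list[GenomicInterval], predictions: list[GenomicInterval]
) -> list[GenomicInterval]:
    """Candidates with zero overlapping bases against every prediction on the
    same contig (the 'excluding overlapping transcripts' intersection)."""
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    by_contig: dict[str, list[GenomicInterval]] = {}
    for p in predictions:
        by_contig.setdefault(p.contig, []).append(p)
    for contig, ivs in by_contig.items():
        ivs.sort(key=lambda iv: iv.start)
        starts, ends = [], []
        for iv in ivs:
            if ends and iv.start < ends[-1]:
                ends[-1] = max(ends[-1], iv.end)
            else:
                starts.append(iv.start)
                ends.append(iv.end)
        merged[contig] = (np.array(starts), np.array(ends))
    out = []
    for c in candidates:
        hit = False
        if c.contig in merged:
            starts, ends = merged[c.contig]
            i = int(np.searchsorted(starts, c.end, side="left"))
            hit = i > 0 and ends[i - 1] > c.start
        if not hit:
            out.append(c)
    return out


@dataclass
class MergeReport:
    kept: int
    removed: int
    removed_ids: list[str] = field(default_factory=list)


def merge_gene_sets(
    genome_genes: dict[str, str],
    novel_transcripts: dict[str, str],
    ortholog_id_map: dict[str, str],
) -> tuple[dict[str, str], MergeReport]:
    """Union of genome-predicted and transcriptome-only gene sets with
    redundancy removal: among entries sharing an ortholog id exactly one
    representative survives (longest sequence, ties by lexicographically
    smaller id); entries without an ortholog id are kept unconditionally."""
    overlap = set(genome_genes) & set(novel_transcripts)
    if overlap:
        raise ValueError(f"duplicate ids across inputs: {sorted(overlap)[:5]}")
    combined = {**genome_genes, **novel_transcripts}
    by_ortholog: dict[str, list[str]] = {}
    for gid in combined:
        oid = ortholog_id_map.get(gid)
        if oid is not None:
            by_ortholog.setdefault(oid, []).append(gid)
    removed: list[str] = []
    for members in by_ortholog.values():
        members.sort(key=lambda g: (-len(combined[g]), g))
        removed.extend(members[1:])
    kept = {g: s for g, s in combined.items() if g not in set(removed)}
    return kept, MergeReport(kept=len(kept), removed=len(removed), removed_ids=sorted(removed))
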