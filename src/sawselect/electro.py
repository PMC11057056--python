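"""Electrosensory-gene characterization: ortholog identification by exact
local alignment, K+-channel pore-motif scanning, FPKM expression, and
splice-junction-based exon-retention calls.

Electroreception in sawfish ampullae of Lorenzini runs through voltage-gated
Ca2+ channels (Cacna1d) and Ca2+-activated / voltage-gated K+ channels (BK,
Shaker).  This module provides the sequence-level checks used to
characterize those channels: a functional K+ channel must carry the
selectivity-filter pore motif (T-x-G-Y-G core), expression is compared on
the FPKM scale, and alternative exon use (the BK channel's alternatively
spliced exon) is quantified from split-read junction counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import AlignmentRecord, GenomicInterval

#: Default pore-motif patterns.  Position syntax: one-letter residues,
#: ``x`` for any residue, ``[...]`` for a residue class; positions joined
#: by ``-``.  Editable configuration, not a claim of a published definition.
DEFAULT_PORE_MOTIFS: dict[str, str] = {
    "K_selectivity_filter": "T-x-G-Y-G",
    "GYG_core": "G-Y-G",
}


def _make_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def local_alignment_score(a: str, b: str) -> float:
    """Smith–Waterman score (BLOSUM62, gap open 11 / extend 1)."""
    return float(_make_aligner("local").score(a, b))


def identify_orthologs(
    query_proteins: dict[str, str],
    target_proteins: dict[str, str],
    min_score: float = 50.0,
) -> pd.DataFrame:
    """All-vs-all local alignment; hits scoring >= ``min_score`` ranked by
    score per query, with a reciprocal-best flag.

    Exact Smith–Waterman rather than a heuristic seeded search: deterministic
    and exhaustive at the scale of curated channel panels.
    """
    if not query_proteins:
        raise ValueError("empty query set")
    if not target_proteins:
        raise ValueError("empty target set")
    scores = {
        (q, t): local_alignment_score(qs, ts)
        for q, qs in query_proteins.items()
        for t, ts in target_proteins.items()
    }
    best_target_of_query = {
        q: max(target_proteins, key=lambda t: (scores[(q, t)], t))
        for q in query_proteins
    }
    best_query_of_target = {
        t: max(query_proteins, key=lambda q: (scores[(q, t)], q))
        for t in target_proteins
    }
    rows = []
    for (q, t), s in scores.items():
        if s < min_score:
            continue
        rows.append(
            {
                "query": q,
                "target": t,
                "score": s,
                "reciprocal_best": best_target_of_query[q] == t
                and best_query_of_target[t] == q,
            }
        )
    df = pd.DataFrame(rows, columns=["query", "target", "score", "reciprocal_best"])
    return df.sort_values(["query", "score"], ascending=[True, False], kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class MotifHit:
    sequence_id: str
    motif: str
    start: int
    matched: str


def _pattern_to_regex(pattern: str) -> re.Pattern:
    parts = pattern.split("-")
    out = []
    for token in parts:
        if token == "x":
            out.append("[A-Z]")
        elif re.fullmatch(r"[A-Z]", token):
            out.append(token)
        elif re.fullmatch(r"\[[A-Z]+\]", token):
            out.append(token)
        else:
            raise ValueError(f"malformed motif token {token!r} in {pattern!r}")
    if not out:
        raise ValueError("empty motif pattern")
    return re.compile("".join(out))


def scan_pore_motif(
    protein: str,
    motif_set: dict[str, str] | None = None,
    sequence_id: str = "",
) -> list[MotifHit]:
    """Non-overlapping matches of each motif pattern, 0-based positions."""
    motifs = DEFAULT_PORE_MOTIFS if motif_set is None else motif_set
    seq = protein.upper()
    hits: list[MotifHit] = []
    for name, pattern in motifs.items():
        rx = _pattern_to_regex(pattern)
        for m in rx.finditer(seq):
            hits.append(MotifHit(sequence_id=sequence_id, motif=name,
                                 start=m.start(), matched=m.group(0)))
    return sorted(hits, key=lambda h: (h.motif, h.start))


def fpkm(count: int, transcript_length_nt: int, total_mapped: int) -> float:
    """Fragments per kilobase of transcript per million mapped reads."""
    if transcript_length_nt <= 0:
        raise ValueError("transcript length must be > 0")
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    return count * 1e9 / (transcript_length_nt * total_mapped)


def fpkm_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add an ``fpkm`` column to a table with ``count``, ``length_nt`` and
    ``total_mapped`` columns."""
    out = counts.copy()
    out["fpkm"] = [
        fpkm(int(r["count"]), int(r["length_nt"]), int(r["total_mapped"]))
        for _, r in out.iterrows()
    ]
    return out


@dataclass
class ExonInclusionResult:
    exon: GenomicInterval
    inclusion_reads: int
    skipping_reads: int
    inclusion_fraction: float | None  # None when no informative junction reads


def exon_inclusion(
    alignment_records: list[AlignmentRecord],
    exon: GenomicInterval,
    flanking_exons: tuple[GenomicInterval, GenomicInterval],
) -> ExonInclusionResult:
    """Count junction reads supporting inclusion vs skipping of ``exon``.

    A record supports skipping when one of its inter-block gaps spans
    exactly from the upstream flank's end to the downstream flank's start;
    it supports inclusion when a gap lands on the exon's start or end
    boundary, or when a block overlaps the exon while the record also joins
    a flank.  Records on other contigs are ignored; each read is counted at
    most once.
    """
    up, down = flanking_exons
    if not (up.contig == exon.contig == down.contig):
        raise ValueError("exon and flanks must share a contig")
    if not (up.end <= exon.start and exon.end <= down.start):
        raise ValueError("exon must lie between the flanking exons")
    incl = skip = 0
    seen: set[str] = set()
    for rec in alignment_records:
        if rec.contig != exon.contig or rec.read_id in seen:
            continue
        gaps = rec.gaps()
        if not gaps:
            continue
        seen.add(rec.read_id)
        if any(g == (up.end, down.start) for g in gaps):
            skip += 1
            continue
        touches_exon = any(g[1] == exon.start or g[0] == exon.end for g in gaps)
        joins_flank = any(g[0] == up.end or g[1] == down.start for g in gaps)
        overlaps_exon = any(
            b.start < exon.end and exon.start < b.end for b in rec.blocks
        )
        if touches_exon or (overlaps_exon and joins_flank):
            incl += 1
    total = incl + skip
    return ExonInclusionResult(
        exon=exon,
        inclusion_reads=incl,
        skipping_reads=skip,
        inclusion_fraction=incl / total if total else None,
    )
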