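"""Codon alignments: back-translation of protein MSAs onto CDS (pal2nal
semantics), gap-column stripping, and substitution classification for the
shared-change conservation tallies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .genetics import CODON_AA, CODON_INDEX, STANDARD_AA, STOP_CODONS

GAP_CODON = "---"

#: Default amino-property partition used by the property-change flag.  The
#: partition is configuration, not a claim about any particular published
#: scheme: hydrophobic / polar-uncharged / basic / acidic.
DEFAULT_PROPERTY_CLASSES: dict[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIMFWC"),
    "polar_uncharged": frozenset("STNQYGP"),
    "basic": frozenset("KRH"),
    "acidic": frozenset("DE"),
}

_DEFAULT_CLASS_OF = {
    aa: name for name, members in DEFAULT_PROPERTY_CLASSES.items() for aa in members
}


@dataclass
class CodonAlignment:
    """Aligned coding sequences; gaps only as whole-codon ``---`` triplets."""

    ids: list[str]
    rows: list[str]
    taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("rows must be equal length")
        if lengths and next(iter(lengths)) % 3:
            raise ValueError("alignment length must be divisible by 3")
        for rid, row in zip(self.ids, self.rows):
            for i in range(0, len(row), 3):
                codon = row[i : i + 3]
                if "-" in codon and codon != GAP_CODON:
                    raise ValueError(
                        f"row {rid}: partial gap codon {codon!r} at nucleotide {i}"
                    )
        if not self.taxa:
            self.taxa = list(self.ids)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def codon(self, row: int, col: int) -> str:
        return self.rows[row][3 * col : 3 * col + 3]

    def column(self, col: int) -> list[str]:
        return [self.codon(i, col) for i in range(len(self.rows))]

    def is_gap_free(self) -> bool:
        return all("-" not in row for row in self.rows)

    def to_fasta(self) -> str:
        return "".join(f">{rid}\n{row}\n" for rid, row in zip(self.ids, self.rows))


def _translate_cds(cds: str) -> str:
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    protein = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        if codon in STOP_CODONS:
            raise ValueError(f"internal stop codon {codon} at nucleotide {i}")
        protein.append(str(Seq(codon).translate()))
    return "".join(protein)


def backtranslate(
    protein_msa: dict[str, str],
    cds_by_id: dict[str, str],
    taxon_by_id: dict[str, str] | None = None,
) -> CodonAlignment:
    """Project a protein MSA onto the underlying coding sequences.

    Every residue column becomes the source codon; protein gaps become
    ``---``.  A terminal stop codon on the CDS is trimmed first.  The CDS
    must translate exactly to the ungapped protein under the standard code.
    """
    ids, rows, taxa = [], [], []
    for sid, aligned in protein_msa.items():
        try:
            cds = cds_by_id[sid].upper()
        except KeyError:
            raise KeyError(f"no CDS for aligned sequence {sid!r}") from None
        if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        ungapped = aligned.replace("-", "")
        if len(cds) != 3 * len(ungapped):
            raise ValueError(
                f"{sid}: CDS length {len(cds)} != 3 x protein length {len(ungapped)}"
            )
        translated = _translate_cds(cds)
        if translated != ungapped.upper():
            mism = next(
                i for i, (a, b) in enumerate(zip(translated, ungapped.upper())) if a != b
            )
            raise ValueError(
                f"{sid}: CDS translation mismatch at residue {mism}: "
                f"{translated[mism]} != {ungapped[mism].upper()}"
            )
        out, k = [], 0
        for aa in aligned:
            if aa == "-":
                out.append(GAP_CODON)
            else:
                out.append(cds[3 * k : 3 * k + 3])
                k += 1
        ids.append(sid)
        rows.append("".join(out))
        taxa.append((taxon_by_id or {}).get(sid, sid))
    return CodonAlignment(ids=ids, rows=rows, taxa=taxa)


def strip_gap_columns(alignment: CodonAlignment) -> CodonAlignment:
    """Drop every codon column containing a gap in any row (pal2nal
    ``-nogap`` semantics); column order preserved."""
    keep = [
        c for c in range(alignment.n_codons)
        if all(codon != GAP_CODON for codon in alignment.column(c))
    ]
    rows = [
        "".join(row[3 * c : 3 * c + 3] for c in keep) for row in alignment.rows
    ]
    return CodonAlignment(ids=list(alignment.ids), rows=rows, taxa=list(alignment.taxa))


def classify_substitution(codon_a: str, codon_b: str) -> str | None:
    """``synonymous`` / ``non-synonymous`` / ``ambiguous``; ``None`` when the
    codons are identical (no substitution to classify)."""
    a, b = codon_a.upper(), codon_b.upper()
    if a not in CODON_INDEX or b not in CODON_INDEX:
        return "ambiguous"
    if a == b:
        return None
    if CODON_AA[CODON_INDEX[a]] == CODON_AA[CODON_INDEX[b]]:
        return "synonymous"
    return "non-synonymous"


def amino_property_change(
    aa_a: str, aa_b: str, class_scheme: dict[str, frozenset[str]] | None = None
) -> bool:
    """True iff the two residues fall in different classes of the property
    partition (default: hydrophobic / polar-uncharged / basic / acidic)."""
    if class_scheme is None:
        class_of = _DEFAULT_CLASS_OF
    else:
        class_of = {aa: name for name, members in class_scheme.items() for aa in members}
    a, b = aa_a.upper(), aa_b.upper()
    for aa in (a, b):
        if aa not in STANDARD_AA or aa not in class_of:
            raise ValueError(f"residue {aa!r} not covered by the property scheme")
    return class_of[a] != class_of[b]


@dataclass
class SubstitutionCall:
    codon_index: int
    codons: dict[str, str]
    classification: str | None
    property_change: bool
    shared_in_focal: bool


@dataclass
class SharedSubstitutionTally:
    """Column-wise tally of changes shared by a focal clade against a
    reference taxon: the fixed-difference pattern behind conservation
    arguments like '18 of 21 changes were non-synonymous'."""

    total_shared: int
    nonsynonymous_shared: int
    property_change_shared: int
    within_focal_variable: int
    calls: list[SubstitutionCall]


def shared_substitution_tally(
    alignment: CodonAlignment,
    focal_taxa: list[str],
    reference_taxon: str,
    class_scheme: dict[str, frozenset[str]] | None = None,
) -> SharedSubstitutionTally:
    """Tally codon columns where all focal taxa share one codon that differs
    from the reference; columns where the focal taxa disagree are counted
    separately as within-focal variation."""
    taxon_row = {t: i for i, t in enumerate(alignment.taxa)}
    for t in [*focal_taxa, reference_taxon]:
        if t not in taxon_row:
            raise KeyError(f"taxon {t!r} not in alignment")
    total = nonsyn = prop = within = 0
    calls: list[SubstitutionCall] = []
    for c in range(alignment.n_codons):
        focal_codons = {t: alignment.codon(taxon_row[t], c) for t in focal_taxa}
        ref = alignment.codon(taxon_row[reference_taxon], c)
        distinct = set(focal_codons.values())
        if len(distinct) > 1:
            within += 1
            continue
        codon = next(iter(distinct))
        cls = classify_substitution(codon, ref)
        if cls is None or cls == "ambiguous":
            continue
        pchange = False
        if cls == "non-synonymous":
            pchange = amino_property_change(
                CODON_AA[CODON_INDEX[codon]], CODON_AA[CODON_INDEX[ref]], class_scheme
            )
        total += 1
        nonsyn += cls == "non-synonymous"
        prop += pchange
        calls.append(
            SubstitutionCall(
                codon_index=c,
                codons={**focal_codons, reference_taxon: ref},
                classification=cls,
                property_change=pchange,
                shared_in_focal=True,
            )
        )
    return SharedSubstitutionTally(
        total_shared=total,
        nonsynonymous_shared=nonsyn,
        property_change_shared=prop,
        within_focal_variable=within,
        calls=calls,
    )
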