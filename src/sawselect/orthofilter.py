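"""Orthogroup curation applied before selection testing: taxon-coverage
filtering, annotation-based paralog splitting, length-outlier removal, a
minimum codon-alignment length gate, and closest-ortholog selection from a
multiple sequence alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

DEFAULT_MAX_DELTA_AA = 100
DEFAULT_MIN_CODONS = 20


@dataclass
class OrthoMember:
    taxon: str
    seq_id: str
    protein: str
    cds: str
    annotation: str | None = None
    domains: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n_codons = len(self.cds) // 3
        if self.cds and len(self.cds) % 3 == 0 and n_codons not in (
            len(self.protein),
            len(self.protein) + 1,  # terminal stop retained
        ):
            raise ValueError(
                f"{self.seq_id}: CDS of {n_codons} codons does not match protein "
                f"length {len(self.protein)}"
            )


@dataclass
class Orthogroup:
    group_id: str
    members: list[OrthoMember]
    ground_truth: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"orthogroup {self.group_id} must have >= 1 member")

    def taxa(self) -> set[str]:
        return {m.taxon for m in self.members}


def filter_taxon_coverage(
    groups: list[Orthogroup], required_taxa: tuple[str, ...]
) -> list[Orthogroup]:
    """Keep only groups with at least one member from every required taxon."""
    if not required_taxa:
        raise ValueError("required_taxa must be non-empty")
    need = set(required_taxa)
    return [g for g in groups if need <= g.taxa()]


def split_paralogs(group: Orthogroup) -> list[Orthogroup]:
    """Partition members by functional-annotation label.  Unlabelled members
    form their own residual subgroup.  Subgroups inherit the group id with a
    label suffix; a group with a single label comes back whole."""
    by_label: dict[str, list[OrthoMember]] = {}
    for m in group.members:
        by_label.setdefault(m.annotation or "unlabelled", []).append(m)
    if len(by_label) == 1:
        return [group]
    return [
        Orthogroup(group_id=f"{group.group_id}|{label}", members=members,
                   ground_truth=dict(group.ground_truth))
        for label, members in sorted(by_label.items())
    ]


def filter_length_outliers(
    group: Orthogroup, max_delta_aa: int = DEFAULT_MAX_DELTA_AA
) -> tuple[Orthogroup | None, list[OrthoMember]]:
    """Discard members whose protein length deviates from the group's mean
    by strictly more than ``max_delta_aa`` residues.  The mean is computed
    once over the pre-filter group (no iterative re-filtering).  Returns the
    surviving group (``None`` if empty) and the removed members."""
    if max_delta_aa < 0:
        raise ValueError("max_delta_aa must be >= 0")
    mean_len = sum(len(m.protein) for m in group.members) / len(group.members)
    kept, removed = [], []
    for m in group.members:
        (kept if abs(len(m.protein) - mean_len) <= max_delta_aa else removed).append(m)
    if not kept:
        return None, removed
    return (
        Orthogroup(group_id=group.group_id, members=kept, ground_truth=dict(group.ground_truth)),
        removed,
    )


def min_alignment_length_filter(codon_alignment, min_codons: int = DEFAULT_MIN_CODONS) -> bool:
    """Pass iff the gap-free alignment is strictly longer than ``min_codons``
    codons ('longer than 20 amino acids')."""
    return codon_alignment.n_codons > min_codons


def pick_closest_ortholog(
    focal_id: str, candidate_ids: list[str], msa: dict[str, str]
) -> tuple[str, float]:
    """Candidate maximizing identical-residue fraction over MSA columns where
    both sequences are ungapped; ties broken by fewer gapped columns, then by
    lexicographically smaller id.  Returns (chosen id, identity)."""
    if not candidate_ids:
        raise ValueError("need at least one candidate")
    try:
        focal = msa[focal_id]
    except KeyError:
        raise KeyError(f"focal sequence {focal_id!r} not in MSA") from None
    ranked = []
    for cid in candidate_ids:
        try:
            cand = msa[cid]
        except KeyError:
            raise KeyError(f"candidate {cid!r} not in MSA") from None
        if len(cand) != len(focal):
            raise ValueError("MSA rows must have equal length")
        both = [(a, b) for a, b in zip(focal, cand) if a != "-" and b != "-"]
        identity = (
            sum(a.upper() == b.upper() for a, b in both) / len(both) if both else 0.0
        )
        n_gapped = sum(1 for a, b in zip(focal, cand) if a == "-" or b == "-")
        ranked.append((-identity, n_gapped, cid))
    ranked.sort()
    best = ranked[0]
    return best[2], -best[0]


@dataclass
class CurationReport:
    input_groups: int
    failed_taxon_coverage: int
    split_into: int
    failed_post_split_coverage: int
    members_removed_by_length: int
    surviving: list[Orthogroup] = field(default_factory=list)


def curate_orthogroups(
    groups: list[Orthogroup],
    required_taxa: tuple[str, ...],
    max_delta_aa: int = DEFAULT_MAX_DELTA_AA,
    recheck_coverage_after_split: bool = True,
) -> CurationReport:
    """Full curation cascade in the order the analysis applies it:
    taxon-coverage filter -> paralog split -> (optional) coverage re-check ->
    length-outlier removal."""
    covered = filter_taxon_coverage(groups, required_taxa)
    n_failed_cov = len(groups) - len(covered)
    split: list[Orthogroup] = []
    for g in covered:
        split.extend(split_paralogs(g))
    if recheck_coverage_after_split:
        post = filter_taxon_coverage(split, required_taxa)
    else:
        post = split
    n_failed_post = len(split) - len(post)
    surviving, removed_members = [], 0
    for g in post:
        kept, removed = filter_length_outliers(g, max_delta_aa)
        removed_members += len(removed)
        if kept is not None and (not required_taxa or set(required_taxa) <= kept.taxa()):
            surviving.append(kept)
    return CurationReport(
        input_groups=len(groups),
        failed_taxon_coverage=n_failed_cov,
        split_into=len(split),
        failed_post_split_coverage=n_failed_post,
        members_removed_by_length=removed_members,
        surviving=surviving,
    )
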