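"""Synthetic-data generators: every input the pipeline consumes, with known
ground truth.

Four generators cover the four data domains of the analysis:

* codon alignments evolved on a species tree under a GY94-type model with
  branch-specific omega mixtures (episodic selection planted on one branch);
* orthogroup collections with controlled rates of paralogy, length outliers
  and missing taxa, flagged so downstream filter decisions can be checked
  against ground truth;
* read alignments over a toy contig with exact per-base depth and
  splice-junction structure;
* three-feature tables (omega, percent sites, delta-GRAVY) with planted
  cluster structure.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AlignmentRecord, GenomicInterval
from .codonalign import CodonAlignment
from .genetics import (
    CODON_AA,
    N_CODONS,
    SENSE_CODONS,
    decode_codons,
    uniform_codon_frequencies,
)
from .gy94 import CodonModel
from .orthofilter import OrthoMember, Orthogroup
from .trees import SpeciesTree

#: Background selective regime used as the study condition when a branch has
#: no planted episodic class: purifying selection typical of conserved
#: coding genes.
DEFAULT_BACKGROUND_OMEGA = 0.2
DEFAULT_KAPPA = 2.5


@dataclass
class CodonModelParams:
    """Per-branch GY94 parameterization: kappa, sense-codon frequencies and
    an omega mixture ``[(omega, weight), ...]`` per branch id."""

    kappa: float = DEFAULT_KAPPA
    codon_frequencies: np.ndarray = field(default_factory=uniform_codon_frequencies)
    branch_mixtures: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        pi = np.asarray(self.codon_frequencies, dtype=float)
        if pi.shape != (N_CODONS,) or np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("codon frequencies must be a 61-vector summing to 1")
        self.codon_frequencies = pi
        for b, mix in self.branch_mixtures.items():
            if any(om < 0 or w < 0 for om, w in mix):
                raise ValueError(f"branch {b}: omegas and weights must be >= 0")
            if abs(sum(w for _, w in mix) - 1.0) > 1e-9:
                raise ValueError(f"branch {b}: mixture weights must sum to 1")

    def mixture_for(self, branch_id: int) -> list[tuple[float, float]]:
        return self.branch_mixtures.get(branch_id, [(DEFAULT_BACKGROUND_OMEGA, 1.0)])


@dataclass
class SimulationConfig:
    tree: SpeciesTree
    params: CodonModelParams
    n_sites: int
    seed: int
    code_table_id: int = 1

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.code_table_id != 1:
            raise ValueError("only the standard genetic code (table 1) is supported")


def simulate_codon_alignment(config: SimulationConfig) -> CodonAlignment:
    """Evolve a gap-free codon alignment down the tree.

    Root codons are drawn from the stationary frequencies; on each branch
    every site independently draws its omega class from that branch's
    mixture and then evolves under the class's transition matrix, with the
    branch normalized to its mixture-averaged mean rate.
    """
    rng = np.random.default_rng(config.seed)
    tree, params, n = config.tree, config.params, config.n_sites
    model = CodonModel(params.kappa, params.codon_frequencies)

    states: dict[int, np.ndarray] = {}
    root = tree.root
    states[root] = rng.choice(N_CODONS, size=n, p=params.codon_frequencies)

    # preorder: parents before children
    for node in reversed(tree.nodes):
        if node.parent is None:
            continue
        parent_state = states[node.parent]
        mixture = params.mixture_for(node.id)
        if node.length == 0.0:
            states[node.id] = parent_state.copy()
            continue
        mats = model.branch_matrices(mixture, node.length)
        weights = np.array([w for _, w in mats])
        classes = rng.choice(len(mats), size=n, p=weights)
        child = np.empty(n, dtype=np.int64)
        for k, (P, _) in enumerate(mats):
            sel = classes == k
            if not sel.any():
                continue
            cum = P[parent_state[sel]].cumsum(axis=1)
            cum[:, -1] = 1.0  # guard rounding
            u = rng.random(sel.sum())
            child[sel] = (u[:, None] > cum).sum(axis=1)
        states[node.id] = child

    ids = list(tree.tip_names)
    rows = [decode_codons(states[tree.tip_id(name)]) for name in ids]
    return CodonAlignment(ids=ids, rows=rows, taxa=list(ids))


# --------------------------------------------------------------------------
# Orthogroup collections
# --------------------------------------------------------------------------

_BASE_PROTEIN_LENGTH = 300
_OUTLIER_EXTRA = 150  # beyond the 100-aa rule once diluted into the group mean


def _random_protein(rng: np.random.Generator, length: int) -> tuple[str, str]:
    """Random protein and a consistent CDS (codon per residue, chosen among
    that residue's sense codons)."""
    codons_of: dict[str, list[str]] = {}
    for codon, aa in zip(SENSE_CODONS, CODON_AA):
        codons_of.setdefault(aa, []).append(codon)
    aas = rng.choice(list(codons_of), size=length)
    cds = "".join(codons_of[aa][rng.integers(len(codons_of[aa]))] for aa in aas)
    return "".join(aas), cds


def simulate_orthogroup_collection(
    n_groups: int,
    taxa: tuple[str, ...],
    paralog_rate: float = 0.0,
    length_outlier_rate: float = 0.0,
    missing_taxon_rate: float = 0.0,
    seed: int = 0,
) -> list[Orthogroup]:
    """Orthogroups with ground-truth defect flags.

    Each group starts as one member per taxon at a common protein length;
    with the given rates it then loses a random taxon (``missing_taxon``),
    gains a co-taxon paralog carrying a distinct annotation label
    (``has_paralogs``), or has one member's length pushed beyond the
    +/-100 aa rule (``has_outlier``).
    """
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    for name, rate in (
        ("paralog_rate", paralog_rate),
        ("length_outlier_rate", length_outlier_rate),
        ("missing_taxon_rate", missing_taxon_rate),
    ):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    groups: list[Orthogroup] = []
    for g in range(n_groups):
        gid = f"OG{g:04d}"
        base_len = int(_BASE_PROTEIN_LENGTH + rng.integers(-10, 11))
        members: list[OrthoMember] = []
        present = list(taxa)
        missing = rng.random() < missing_taxon_rate
        if missing:
            present.remove(taxa[rng.integers(len(taxa))])
        outlier = rng.random() < length_outlier_rate and len(present) >= 2
        outlier_taxon = present[rng.integers(len(present))] if outlier else None
        for taxon in present:
            length = base_len
            if taxon == outlier_taxon:
                length = base_len + _OUTLIER_EXTRA * int(rng.choice([-1, 1]))
                length = max(length, 30)
            protein, cds = _random_protein(rng, length)
            members.append(
                OrthoMember(
                    taxon=taxon,
                    seq_id=f"{gid}_{taxon}",
                    protein=protein,
                    cds=cds,
                    annotation=gid,
                )
            )
        paralog = rng.random() < paralog_rate and bool(present)
        if paralog:
            taxon = present[rng.integers(len(present))]
            protein, cds = _random_protein(rng, base_len)
            members.append(
                OrthoMember(
                    taxon=taxon,
                    seq_id=f"{gid}_{taxon}_p2",
                    protein=protein,
                    cds=cds,
                    annotation=f"{gid}_dup",
                )
            )
        groups.append(
            Orthogroup(
                group_id=gid,
                members=members,
                ground_truth={
                    "has_paralogs": bool(paralog),
                    "has_outlier": bool(outlier),
                    "missing_taxon": bool(missing),
                },
            )
        )
    return groups


# --------------------------------------------------------------------------
# Read alignments over a toy contig
# --------------------------------------------------------------------------


@dataclass
class JunctionSpec:
    """A split-read template: two exonic blocks joined over an intron gap."""

    left_block: tuple[int, int]
    right_block: tuple[int, int]
    count: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.left_block[1] > self.right_block[0]:
            raise ValueError("junction blocks must be ordered and non-overlapping")
        if self.count < 0:
            raise ValueError("count must be >= 0")


def simulate_read_alignments(
    contig_length: int,
    intervals_with_depth: list[tuple[int, int, int]] | None = None,
    mapq_per_read: int = 60,
    junction_spec: list[JunctionSpec] | None = None,
    seed: int = 0,
    contig: str = "contig1",
) -> list[AlignmentRecord]:
    """Emit alignment records realizing an exact per-base depth profile plus
    optional split junction reads.

    Each ``(start, end, depth)`` request emits ``depth`` single-block records
    spanning exactly ``[start, end)``, so accepted-read coverage equals the
    requested profile by construction.  Junction specs emit two-block records
    whose gap spans exactly the requested intron.
    """
    del seed  # records are fully determined by the request; kept for API symmetry
    records: list[AlignmentRecord] = []
    serial = 0
    for start, end, depth in intervals_with_depth or []:
        if depth < 0:
            raise ValueError("depth must be >= 0")
        if not (0 <= start < end <= contig_length):
            raise ValueError(f"interval [{start}, {end}) outside contig of length {contig_length}")
        for _ in range(depth):
            records.append(
                AlignmentRecord(
                    read_id=f"read{serial:06d}",
                    contig=contig,
                    blocks=[GenomicInterval(contig, start, end)],
                    mapq=mapq_per_read,
                )
            )
            serial += 1
    for spec in junction_spec or []:
        for block in (spec.left_block, spec.right_block):
            if not (0 <= block[0] < block[1] <= contig_length):
                raise ValueError(f"junction block {block} outside contig")
        for _ in range(spec.count):
            records.append(
                AlignmentRecord(
                    read_id=f"read{serial:06d}",
                    contig=contig,
                    blocks=[
                        GenomicInterval(contig, *spec.left_block),
                        GenomicInterval(contig, *spec.right_block),
                    ],
                    mapq=spec.mapq,
                )
            )
            serial += 1
    return records


# --------------------------------------------------------------------------
# Planted-cluster PSG feature tables
# --------------------------------------------------------------------------


def simulate_psg_features(
    sizes: tuple[int, ...],
    centroids: list[tuple[float, float, float]],
    sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gene-level (omega, percent_sites, delta_gravy) features with planted
    Gaussian clusters; ``true_cluster`` carries the ground-truth label."""
    if not sizes:
        raise ValueError("sizes must be non-empty")
    if len(sizes) != len(centroids):
        raise ValueError("sizes and centroids must have equal length")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    gene = 0
    for label, (size, centroid) in enumerate(zip(sizes, centroids)):
        c = np.asarray(centroid, dtype=float)
        for _ in range(size):
            x = c + rng.normal(0.0, sd, size=3)
            rows.append(
                {
                    "gene_id": f"gene{gene:04d}",
                    "omega": x[0],
                    "percent_sites": x[1],
                    "delta_gravy": x[2],
                    "true_cluster": label,
                }
            )
            gene += 1
    return pd.DataFrame(rows)
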