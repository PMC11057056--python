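"""Genetic-code tables and codon-level primitives shared across the package.

The standard nuclear code is used throughout: 61 sense codons, stop codons
excluded from every model's state space.  Codon order is lexicographic over
the alphabet ACGT and is the canonical index used by the substitution model,
the simulator and the likelihood engine.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data import CodonTable

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

NUCLEOTIDES = "ACGT"

#: 61 sense codons of the standard code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(NUCLEOTIDES, repeat=3))
    if c not in _STANDARD.stop_codons
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
N_CODONS = len(SENSE_CODONS)  # 61

STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

#: amino acid (one-letter) encoded by each sense codon, aligned to SENSE_CODONS.
CODON_AA: tuple[str, ...] = tuple(_STANDARD.forward_table[c] for c in SENSE_CODONS)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# --- pairwise codon structure used by the GY94 rate matrix -------------------
_codon_mat = np.array(
    [[NUCLEOTIDES.index(nt) for nt in codon] for codon in SENSE_CODONS], dtype=np.int8
)
_ndiff = (_codon_mat[:, None, :] != _codon_mat[None, :, :]).sum(axis=2)

#: boolean (61, 61): codon pairs differing at exactly one nucleotide position.
SINGLE_NT_DIFF: np.ndarray = _ndiff == 1

_diff_pos = np.argmax(_codon_mat[:, None, :] != _codon_mat[None, :, :], axis=2)
_from_nt = np.take_along_axis(
    np.broadcast_to(_codon_mat[:, None, :], _ndiff.shape + (3,)), _diff_pos[..., None], 2
)[..., 0]
_to_nt = np.take_along_axis(
    np.broadcast_to(_codon_mat[None, :, :], _ndiff.shape + (3,)), _diff_pos[..., None], 2
)[..., 0]
# transitions: A<->G (indices 0, 2) and C<->T (indices 1, 3)
IS_TRANSITION: np.ndarray = SINGLE_NT_DIFF & (
    (np.minimum(_from_nt, _to_nt) == 0) & (np.maximum(_from_nt, _to_nt) == 2)
    | (np.minimum(_from_nt, _to_nt) == 1) & (np.maximum(_from_nt, _to_nt) == 3)
)

_aa_arr = np.array(CODON_AA)
#: boolean (61, 61): pairs encoding different amino acids.
IS_NONSYNONYMOUS: np.ndarray = _aa_arr[:, None] != _aa_arr[None, :]

del _codon_mat, _ndiff, _diff_pos, _from_nt, _to_nt, _aa_arr


def uniform_codon_frequencies() -> np.ndarray:
    """Uniform 1/61 frequencies over the sense codons."""
    return np.full(N_CODONS, 1.0 / N_CODONS)


def f3x4_frequencies(nt_freqs_by_position: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from a (3, 4) table of per-position nucleotide
    frequencies (columns ordered ACGT), renormalized over sense codons."""
    f = np.asarray(nt_freqs_by_position, dtype=float)
    if f.shape != (3, 4):
        raise ValueError("expected a (3, 4) nucleotide frequency table")
    if np.any(f < 0) or not np.allclose(f.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each row must be a probability vector over ACGT")
    pi = np.array(
        [
            f[0, NUCLEOTIDES.index(c[0])]
            * f[1, NUCLEOTIDES.index(c[1])]
            * f[2, NUCLEOTIDES.index(c[2])]
            for c in SENSE_CODONS
        ]
    )
    total = pi.sum()
    if total <= 0:
        raise ValueError("frequency table puts zero mass on all sense codons")
    return pi / total


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; raises on stop/ambiguous."""
    codon = codon.upper()
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no amino acid")
    try:
        return CODON_AA[CODON_INDEX[codon]]
    except KeyError:
        raise ValueError(f"not an unambiguous sense codon: {codon!r}") from None


def encode_codons(seq: str) -> np.ndarray:
    """Codon-index vector for an ungapped CDS (length divisible by 3)."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    seq = seq.upper()
    try:
        return np.array(
            [CODON_INDEX[seq[i : i + 3]] for i in range(0, len(seq), 3)], dtype=np.int64
        )
    except KeyError as exc:
        raise ValueError(f"stop or ambiguous codon in sequence: {exc.args[0]}") from None


def decode_codons(indices: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in np.asarray(indices))
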