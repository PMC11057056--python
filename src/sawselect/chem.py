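"""Per-residue biochemical profiling: Kyte–Doolittle hydropathy and
Zimmerman polarity scales, sliding-window profiles, GRAVY, and pairwise
delta profiles with alignment-mediated gap correction.

Delta profiles are stored as focal minus reference; report writers that
follow the skate-minus-sawfish orientation negate on output and record the
sign convention in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.SeqUtils.ProtParamData import kd as _biopython_kd

from .orthofilter import pick_closest_ortholog

#: Kyte & Doolittle hydropathy (positive = hydrophobic).
KYTE_DOOLITTLE: dict[str, float] = dict(_biopython_kd)

#: Zimmerman polarity.
ZIMMERMAN_POLARITY: dict[str, float] = {
    "A": 0.00, "R": 52.00, "N": 3.38, "D": 49.70, "C": 1.48,
    "Q": 3.53, "E": 49.90, "G": 0.00, "H": 51.60, "I": 0.13,
    "L": 0.13, "K": 49.50, "M": 1.43, "F": 0.35, "P": 1.58,
    "S": 1.67, "T": 1.66, "W": 2.10, "Y": 1.61, "V": 0.13,
}

SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": KYTE_DOOLITTLE,
    "zimmerman_polarity": ZIMMERMAN_POLARITY,
}


def _lookup(sequence: str, table: dict[str, float]) -> np.ndarray:
    try:
        return np.array([table[aa] for aa in sequence.upper()])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None


@dataclass
class ResidueProfile:
    sequence_id: str
    scale: str
    window: int
    values: np.ndarray


def scale_profile(
    sequence: str, scale: str = "kyte_doolittle", window: int = 1,
    sequence_id: str = "",
) -> ResidueProfile:
    """Windowed-mean scale profile.

    Position i carries the mean scale value over the window centred on it;
    edge positions where the full window does not fit carry the raw residue
    value.  Window must be odd and no longer than the sequence.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > len(sequence):
        raise ValueError("window longer than sequence")
    table = SCALES[scale] if scale in SCALES else None
    if table is None:
        raise ValueError(f"unknown scale {scale!r}; options: {sorted(SCALES)}")
    raw = _lookup(sequence, table)
    values = raw.copy()
    half = window // 2
    if window > 1 and len(raw) >= window:
        smoothed = np.convolve(raw, np.full(window, 1.0 / window), mode="valid")
        values[half : len(raw) - half] = smoothed
    return ResidueProfile(sequence_id=sequence_id, scale=scale, window=window, values=values)


def gravy(sequence: str) -> float:
    """Grand average of hydropathy: mean Kyte–Doolittle value."""
    if not sequence:
        raise ValueError("empty sequence")
    return float(_lookup(sequence, KYTE_DOOLITTLE).mean())


def _global_align(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = next(iter(aligner.align(a, b)))
    return aln[0], aln[1]


@dataclass
class ProfileDelta:
    """Per-aligned-column scale deltas between a focal and reference protein.

    ``delta`` is focal - reference, NaN where masked; ``mask`` is True on
    columns where either sequence is gapped.
    """

    focal_id: str
    reference_id: str
    scale: str
    window: int
    aligned_focal: str
    aligned_reference: str
    focal_values: np.ndarray     # NaN at focal gaps
    reference_values: np.ndarray
    delta: np.ndarray
    mask: np.ndarray
    domains: list[tuple[str, int, int]] = field(default_factory=list)
    sign_convention: str = "focal_minus_reference"


def delta_profile(
    focal_seq: str,
    ref_seq: str,
    alignment: tuple[str, str] | None = None,
    scale: str = "kyte_doolittle",
    window: int = 1,
    focal_id: str = "focal",
    reference_id: str = "reference",
    domains: list[tuple[str, int, int]] | None = None,
) -> ProfileDelta:
    """Column-wise scale difference between two proteins.

    Profiles are computed on the ungapped sequences and then mapped through
    the pairwise alignment (the gap-correction step); columns gapped in
    either row are masked.  If no alignment is supplied, a global
    BLOSUM62/affine alignment is computed.
    """
    if alignment is None:
        alignment = _global_align(focal_seq, ref_seq)
    a_focal, a_ref = alignment
    if len(a_focal) != len(a_ref):
        raise ValueError("aligned rows must have equal length")
    if a_focal.replace("-", "") != focal_seq or a_ref.replace("-", "") != ref_seq:
        raise ValueError("alignment rows do not match the input sequences")
    prof_f = scale_profile(focal_seq, scale, window).values
    prof_r = scale_profile(ref_seq, scale, window).values
    n = len(a_focal)
    fvals = np.full(n, np.nan)
    rvals = np.full(n, np.nan)
    i = j = 0
    for c in range(n):
        if a_focal[c] != "-":
            fvals[c] = prof_f[i]
            i += 1
        if a_ref[c] != "-":
            rvals[c] = prof_r[j]
            j += 1
    mask = np.isnan(fvals) | np.isnan(rvals)
    delta = np.where(mask, np.nan, fvals - rvals)
    return ProfileDelta(
        focal_id=focal_id,
        reference_id=reference_id,
        scale=scale,
        window=window,
        aligned_focal=a_focal,
        aligned_reference=a_ref,
        focal_values=fvals,
        reference_values=rvals,
        delta=delta,
        mask=mask,
        domains=domains or [],
    )


def delta_gravy(
    focal_id: str, candidate_ids: list[str], msa: dict[str, str]
) -> tuple[float, str]:
    """GRAVY(focal) - GRAVY(closest-aligning candidate), both computed on
    the ungapped sequences; returns (delta, chosen reference id)."""
    ref_id, _ = pick_closest_ortholog(focal_id, candidate_ids, msa)
    focal = msa[focal_id].replace("-", "")
    ref = msa[ref_id].replace("-", "")
    return gravy(focal) - gravy(ref), ref_id
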