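"""GY94-type codon substitution model and Felsenstein pruning likelihood.

The rate matrix follows the Goldman–Yang form: only single-nucleotide codon
changes have nonzero rate; a change i -> j gets rate ``pi_j * kappa^[ts] *
omega^[nonsyn]``.  The chain is reversible with stationary distribution
``pi``, so the matrix is symmetrizable and transition probabilities are
computed from one symmetric eigendecomposition per (kappa, omega) pair —
afterwards P(t) for any t costs two 61x61 matrix products.  That is what
makes whole-gene optimization affordable: an objective evaluation needs at
most three eigendecompositions (one per distinct omega) regardless of the
number of branches.

Branch lengths are expected substitutions per codon site under the branch's
own model: each branch's matrix is normalized by the mean rate of its omega
mixture before exponentiation.

Per-site rate mixtures enter in random-effects style: the likelihood of a
site is the mixture-weight average over full prunings that differ only in
the transition matrix assigned to the test branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh

from .genetics import (
    IS_NONSYNONYMOUS,
    IS_TRANSITION,
    N_CODONS,
    SINGLE_NT_DIFF,
    encode_codons,
    uniform_codon_frequencies,
)
from .trees import SpeciesTree


def rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """Unnormalized GY94 generator (61 x 61); rows sum to zero."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if omega < 0:
        raise ValueError("omega must be >= 0")
    factor = np.where(IS_TRANSITION, kappa, 1.0) * np.where(IS_NONSYNONYMOUS, omega, 1.0)
    Q = np.where(SINGLE_NT_DIFF, factor, 0.0) * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def mean_rate(kappa: float, omega: float, pi: np.ndarray) -> float:
    """Expected substitutions per codon per unit time, -sum_i pi_i Q_ii."""
    Q = rate_matrix(kappa, omega, pi)
    return float(-(pi * np.diag(Q)).sum())


@dataclass
class _Eig:
    evals: np.ndarray  # (61,)
    right: np.ndarray  # D^-1 V, columns are right eigenvectors of Q
    left: np.ndarray   # V^T D, rows are left eigenvectors
    mu: float          # mean rate of the unnormalized generator


class CodonModel:
    """GY94 model with fixed kappa and codon frequencies.

    Caches the symmetric eigendecomposition per omega so that transition
    matrices for many branch lengths are cheap.
    """

    def __init__(self, kappa: float, pi: np.ndarray | None = None):
        pi = uniform_codon_frequencies() if pi is None else np.asarray(pi, dtype=float)
        if pi.shape != (N_CODONS,):
            raise ValueError(f"pi must have length {N_CODONS}")
        if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must be strictly positive and sum to 1")
        self.kappa = float(kappa)
        self.pi = pi
        self._sqrt_pi = np.sqrt(pi)
        self._cache: dict[float, _Eig] = {}

    def _eig(self, omega: float) -> _Eig:
        key = float(omega)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        Q = rate_matrix(self.kappa, key, self.pi)
        d = self._sqrt_pi
        S = Q * (d[:, None] / d[None, :])
        S = 0.5 * (S + S.T)  # symmetrize away rounding noise
        evals, V = eigh(S)
        eig = _Eig(
            evals=evals,
            right=V / d[:, None],
            left=V.T * d[None, :],
            mu=float(-(self.pi * np.diag(Q)).sum()),
        )
        if len(self._cache) > 64:
            self._cache.clear()
        self._cache[key] = eig
        return eig

    def transition_matrix(self, omega: float, t: float, rate_norm: float | None = None) -> np.ndarray:
        """P(t) with the generator scaled to unit mean rate.

        ``rate_norm`` overrides the normalization constant — used when the
        branch hosts an omega mixture and must be normalized by the
        mixture-averaged rate rather than this class's own mean rate.
        """
        if t < 0:
            raise ValueError("branch length must be >= 0")
        e = self._eig(omega)
        mu = e.mu if rate_norm is None else rate_norm
        if mu <= 0:
            raise ValueError("rate normalization must be positive")
        P = (e.right * np.exp(e.evals * (t / mu))) @ e.left
        np.maximum(P, 0.0, out=P)
        return P

    def mixture_rate(self, mixture: list[tuple[float, float]]) -> float:
        """Mean rate of a branch whose sites draw omega from ``mixture``
        (list of (omega, weight))."""
        return float(sum(w * self._eig(om).mu for om, w in mixture))

    def branch_matrices(
        self, mixture: list[tuple[float, float]], t: float
    ) -> list[tuple[np.ndarray, float]]:
        """Per-class transition matrices for a mixture branch, all normalized
        by the mixture-averaged rate so that t is expected substitutions per
        codon averaged over sites."""
        r = self.mixture_rate(mixture)
        return [(self.transition_matrix(om, t, rate_norm=r), w) for om, w in mixture]


class PrunedAlignment:
    """Site-pattern-compressed codon alignment bound to a tree, with the
    Felsenstein pruning recursion vectorized over patterns."""

    def __init__(self, tree: SpeciesTree, sequences: dict[str, str]):
        self.tree = tree
        missing = set(tree.tip_names) - set(sequences)
        if missing:
            raise ValueError(f"alignment missing tree tips: {sorted(missing)}")
        codes = np.stack([encode_codons(sequences[name]) for name in tree.tip_names])
        if len({len(s) for s in sequences.values()}) != 1:
            raise ValueError("sequences must have equal length")
        patterns, inverse, counts = np.unique(
            codes.T, axis=0, return_inverse=True, return_counts=True
        )
        self.n_sites = codes.shape[1]
        self.patterns = patterns.T  # (ntips, npat)
        self.weights = counts.astype(float)
        self.pattern_of_site = inverse
        self._tip_row = {tid: i for i, tid in enumerate(tree.tip_ids)}

    def site_pattern_likelihoods(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray) -> np.ndarray:
        """Likelihood of each site pattern given one transition matrix per
        non-root node (keyed by node id)."""
        npat = self.patterns.shape[1]
        partial: dict[int, np.ndarray] = {}
        for node in self.tree.nodes:
            if node.is_tip:
                continue
            prod = np.ones((npat, N_CODONS))
            for cid in node.children:
                P = P_by_branch[cid]
                child = self.tree.nodes[cid]
                if child.is_tip:
                    msg = P.T[self.patterns[self._tip_row[cid]]]
                else:
                    msg = partial.pop(cid) @ P.T
                prod *= msg
            partial[node.id] = prod
        return partial[self.tree.root] @ pi

    def log_likelihood(self, P_by_branch: dict[int, np.ndarray], pi: np.ndarray) -> float:
        lik = self.site_pattern_likelihoods(P_by_branch, pi)
        if np.any(lik <= 0):
            return -np.inf
        return float(self.weights @ np.log(lik))

    def log_likelihood_mixture(
        self,
        P_by_branch: dict[int, np.ndarray],
        pi: np.ndarray,
        mixture_branch: int,
        class_matrices: list[tuple[np.ndarray, float]],
    ) -> float:
        """Random-effects mixture on one branch: per site, the likelihood is
        the weight-average over prunings that differ only in that branch's
        transition matrix."""
        mix = np.zeros(self.patterns.shape[1])
        for P, w in class_matrices:
            if w == 0.0:
                continue
            assignment = dict(P_by_branch)
            assignment[mixture_branch] = P
            mix += w * self.site_pattern_likelihoods(assignment, pi)
        if np.any(mix <= 0):
            return -np.inf
        return float(self.weights @ np.log(mix))


def log_likelihood(
    alignment,
    tree: SpeciesTree,
    kappa: float,
    pi: np.ndarray | None,
    branch_omegas: dict[int, list[tuple[float, float]]],
    branch_lengths: dict[int, float] | None = None,
) -> float:
    """Log-likelihood of a gap-free codon alignment on ``tree``.

    ``branch_omegas`` maps node id to an omega mixture ``[(omega, weight),
    ...]``; a single-class branch is ``[(omega, 1.0)]``.  At most one branch
    may carry a multi-class mixture (the branch under test).  Branch lengths
    default to the tree's own.
    """
    from .codonalign import CodonAlignment  # local import to avoid a cycle

    if isinstance(alignment, CodonAlignment):
        sequences = dict(zip(alignment.ids, alignment.rows))
    else:
        sequences = dict(alignment)
    model_pi = uniform_codon_frequencies() if pi is None else np.asarray(pi, float)
    pruned = PrunedAlignment(tree, sequences)
    model = CodonModel(kappa, model_pi)
    lengths = branch_lengths or {}
    multi = [b for b, mix in branch_omegas.items() if len(mix) > 1]
    if len(multi) > 1:
        raise ValueError("at most one branch may carry a multi-class mixture")
    for b, mix in branch_omegas.items():
        total = sum(w for _, w in mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights on branch {b} sum to {total}, not 1")
    P_by_branch = {}
    for b in tree.branch_ids():
        mix = branch_omegas[b]
        if len(mix) == 1:
            t = lengths.get(b, tree.nodes[b].length)
            P_by_branch[b] = model.transition_matrix(mix[0][0], t)
    if multi:
        b = multi[0]
        t = lengths.get(b, tree.nodes[b].length)
        mats = model.branch_matrices(branch_omegas[b], t)
        return pruned.log_likelihood_mixture(P_by_branch, model_pi, b, mats)
    return pruned.log_likelihood(P_by_branch, model_pi)
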