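"""Branch-specific episodic positive-selection testing.

The test is a two-class random-effects simplification of the adaptive
branch-site framework: on the branch under test, each site independently
belongs to a conserved class (omega1 in [0, 1]) or an unconstrained class
(omega2 in [0, omega_cap]) with free weight; background branches share a
single omega.  The null constrains omega2 <= 1, so positive selection is
detected by a likelihood-ratio test whose statistic is referred to the
boundary mixture 1/2 chi2(1) + 1/2 chi2(2).

Fitting is two-stage: branch lengths and kappa are estimated once per gene
under a single-omega model and held fixed during every per-branch test,
which decouples the per-branch optimizations and keeps the model
identifiable at single-gene alignments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .codonalign import CodonAlignment
from .gy94 import CodonModel, PrunedAlignment
from .trees import SpeciesTree

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_OMEGA_CAP = 10_000.0
_LOG_OMEGA_MIN = np.log(1e-4)
_LL_TOL = 1e-6


@dataclass
class GlobalFit:
    """Single-omega fit of kappa, omega and branch lengths for one gene."""

    kappa: float
    omega: float
    branch_lengths: dict[int, float]
    log_likelihood: float
    converged: bool = True


@dataclass
class ModelFit:
    log_likelihood: float
    omega1: float
    omega2: float
    weight2: float  # proportion of sites in the omega2 class
    background_omega: float
    converged: bool = True


@dataclass
class BranchTestResult:
    gene_id: str
    branch_id: int
    branch_name: str
    null_loglik: float
    alt_loglik: float
    lrt: float
    p_value: float
    corrected_p: float | None
    omega1: float
    omega2: float
    weight2: float
    background_omega: float
    omega_capped: bool
    converged: bool = True

    @property
    def percent_sites(self) -> float:
        """Percentage of sites in the unconstrained (omega2) class."""
        return 100.0 * self.weight2


def _root_edge_groups(tree: SpeciesTree) -> list[list[int]]:
    """Branch-length parameter groups: the two root-child edges share one
    parameter (their lengths are confounded under a reversible model); every
    other branch gets its own."""
    root_children = tree.nodes[tree.root].children
    groups = [list(root_children)]
    groups.extend([b] for b in tree.branch_ids() if b not in root_children)
    return groups


def fit_global(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    init_kappa: float = 2.0,
    init_omega: float = 0.3,
    max_branch_length: float = 20.0,
) -> GlobalFit:
    """Stage-1 fit: one omega for the whole tree, free kappa and branch
    lengths (initialized from the tree's own lengths)."""
    pruned = PrunedAlignment(tree, dict(zip(alignment.ids, alignment.rows)))
    groups = _root_edge_groups(tree)
    init_lengths = []
    ratios = []
    for grp in groups:
        total = sum(tree.nodes[b].length for b in grp)
        init_lengths.append(max(total, 1e-3))
        if len(grp) > 1:
            ratios.append(
                [tree.nodes[b].length / total if total > 0 else 1.0 / len(grp) for b in grp]
            )
        else:
            ratios.append([1.0])

    def unpack(x: np.ndarray) -> tuple[float, float, dict[int, float]]:
        kappa, omega = np.exp(x[0]), np.exp(x[1])
        lengths: dict[int, float] = {}
        for grp, r, lx in zip(groups, ratios, x[2:]):
            total = np.exp(lx)
            for b, frac in zip(grp, r):
                lengths[b] = total * frac
        return kappa, omega, lengths

    def objective(x: np.ndarray) -> float:
        kappa, omega, lengths = unpack(x)
        model = CodonModel(kappa)
        try:
            P = {b: model.transition_matrix(omega, lengths[b]) for b in tree.branch_ids()}
        except (ValueError, FloatingPointError):
            return 1e10
        ll = pruned.log_likelihood(P, model.pi)
        return 1e10 if not np.isfinite(ll) else -ll

    x0 = np.concatenate(
        ([np.log(init_kappa), np.log(init_omega)], np.log(init_lengths))
    )
    bounds = [(np.log(0.1), np.log(50.0)), (_LOG_OMEGA_MIN, np.log(50.0))] + [
        (np.log(1e-6), np.log(max_branch_length))
    ] * len(groups)
    res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 300, "ftol": 1e-10})
    kappa, omega, lengths = unpack(res.x)
    return GlobalFit(
        kappa=kappa,
        omega=omega,
        branch_lengths=lengths,
        log_likelihood=-res.fun,
        converged=bool(res.success),
    )


class _BranchObjective:
    """Negative log-likelihood for the per-branch two-class model with kappa
    and branch lengths fixed; caches background transition matrices per
    background-omega value."""

    def __init__(
        self,
        pruned: PrunedAlignment,
        tree: SpeciesTree,
        test_branch: int,
        kappa: float,
        branch_lengths: dict[int, float],
    ):
        self.pruned = pruned
        self.tree = tree
        self.test_branch = test_branch
        self.model = CodonModel(kappa)
        self.lengths = branch_lengths
        self.background = [b for b in tree.branch_ids() if b != test_branch]
        self._bg_cache: dict[float, dict[int, np.ndarray]] = {}

    def _background_P(self, bg_omega: float) -> dict[int, np.ndarray]:
        key = round(float(bg_omega), 12)
        hit = self._bg_cache.get(key)
        if hit is None:
            hit = {
                b: self.model.transition_matrix(bg_omega, self.lengths[b])
                for b in self.background
            }
            if len(self._bg_cache) > 200:
                self._bg_cache.clear()
            self._bg_cache[key] = hit
        return hit

    def loglik(self, bg_omega: float, omega1: float, omega2: float, weight2: float) -> float:
        mixture = [(omega1, 1.0 - weight2), (omega2, weight2)]
        mats = self.model.branch_matrices(mixture, self.lengths[self.test_branch])
        return self.pruned.log_likelihood_mixture(
            self._background_P(bg_omega), self.model.pi, self.test_branch, mats
        )

    def neg(self, x: np.ndarray) -> float:
        bg, w1, lw2, w = np.exp(x[0]), x[1], np.exp(x[2]), x[3]
        try:
            ll = self.loglik(bg, w1, lw2, w)
        except (ValueError, FloatingPointError):
            return 1e10
        return 1e10 if not np.isfinite(ll) else -ll


def _optimize(obj: _BranchObjective, x0: np.ndarray, bounds) -> tuple[float, np.ndarray]:
    res = minimize(obj.neg, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": 200, "ftol": 1e-10})
    return -obj.neg(res.x), res.x


def fit_branch_models(
    alignment: CodonAlignment,
    tree: SpeciesTree,
    test_branch: int | str,
    global_fit: GlobalFit | None = None,
    omega_cap: float = DEFAULT_OMEGA_CAP,
    max_restarts: int = 3,
) -> tuple[ModelFit, ModelFit]:
    """Fit null (omega2 <= 1) and alternative (omega2 <= omega_cap) two-class
    models on the test branch.  Extra optimizer starts are spent only when
    the nesting inequality alt >= null is violated, up to ``max_restarts``
    starts per model."""
    if isinstance(test_branch, str):
        test_branch = tree.tip_id(test_branch)
    if global_fit is None:
        global_fit = fit_global(alignment, tree)
    pruned = PrunedAlignment(tree, dict(zip(alignment.ids, alignment.rows)))
    obj = _BranchObjective(pruned, tree, test_branch, global_fit.kappa, global_fit.branch_lengths)

    log_bg0 = np.log(np.clip(global_fit.omega, 1e-4, 50.0))
    w1_0 = float(np.clip(global_fit.omega, 1e-3, 0.999))

    # --- null: omega2 bounded at 1 ---
    null_bounds = [
        (_LOG_OMEGA_MIN, np.log(50.0)),  # log background omega
        (0.0, 1.0),                      # omega1
        (_LOG_OMEGA_MIN, 0.0),           # log omega2 (<= 1)
        (1e-6, 1.0 - 1e-6),              # weight of omega2 class
    ]
    null_starts = [
        np.array([log_bg0, w1_0, np.log(min(max(global_fit.omega, 1e-3), 1.0)), 0.5]),
        np.array([log_bg0, 0.05, np.log(1.0), 0.2]),
        np.array([log_bg0, w1_0, np.log(0.5), 0.8]),
    ]
    null_ll, null_x = max(
        (_optimize(obj, s, null_bounds) for s in null_starts[:2]), key=lambda t: t[0]
    )

    # --- alternative: omega2 free up to the cap ---
    alt_bounds = list(null_bounds)
    alt_bounds[2] = (_LOG_OMEGA_MIN, np.log(omega_cap))
    alt_starts = [
        np.array([null_x[0], null_x[1], np.log(2.0), max(null_x[3], 0.05)]),
        np.array([log_bg0, w1_0, np.log(20.0), 0.1]),
        null_x.copy(),
    ]
    best_alt = (-np.inf, alt_starts[0])
    for i, start in enumerate(alt_starts):
        ll, x = _optimize(obj, start, alt_bounds)
        if ll > best_alt[0]:
            best_alt = (ll, x)
        if i + 1 >= 2 and best_alt[0] >= null_ll - _LL_TOL:
            break
        if i + 1 >= max_restarts:
            break
    alt_ll, alt_x = best_alt

    # Remaining null starts only if nesting is still violated from the null side
    if alt_ll < null_ll - _LL_TOL:
        for s in null_starts[2:]:
            ll, x = _optimize(obj, s, null_bounds)
            if ll > null_ll:
                null_ll, null_x = ll, x
    converged = alt_ll >= null_ll - 1e-3
    if not converged:
        logger.warning(
            "branch %s: alternative fit below null (%.6f < %.6f); flagged",
            test_branch, alt_ll, null_ll,
        )

    def to_fit(ll: float, x: np.ndarray) -> ModelFit:
        return ModelFit(
            log_likelihood=ll,
            omega1=float(x[1]),
            omega2=float(np.exp(x[2])),
            weight2=float(x[3]),
            background_omega=float(np.exp(x[0])),
            converged=converged,
        )

    return to_fit(null_ll, null_x), to_fit(alt_ll, alt_x)


def lrt_pvalue(null_ll: float, alt_ll: float, tol: float = 1e-4) -> float:
    """Boundary-mixture p-value: LRT = 2(alt - null) referred to
    1/2 chi2(1) + 1/2 chi2(2)."""
    lrt = 2.0 * (alt_ll - null_ll)
    if lrt < -tol:
        raise ValueError(f"negative LRT {lrt:.6g} beyond tolerance")
    lrt = max(lrt, 0.0)
    p = 0.5 * chi2.sf(lrt, 1) + 0.5 * chi2.sf(lrt, 2)
    return float(min(max(p, 0.0), 1.0))


def holm_bonferroni(p_values) -> np.ndarray:
    """Holm step-down familywise-error-rate adjustment, original order
    preserved: sorted ascending, the i-th smallest p is scaled by (m - i),
    a running maximum enforces monotonicity, and values are clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum((m - np.arange(m)) * p[order], 1.0)
    adjusted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adjusted
    return out


def test_gene(
    gene_id: str,
    alignment: CodonAlignment,
    tree: SpeciesTree,
    branches: list[int | str] | None = None,
    omega_cap: float = DEFAULT_OMEGA_CAP,
) -> list[BranchTestResult]:
    """Run the episodic-selection test on each requested branch of one gene
    (default: every terminal branch), sharing the stage-1 fit."""
    gfit = fit_global(alignment, tree)
    if branches is None:
        branches = list(tree.tip_names)
    out = []
    for br in branches:
        bid = tree.tip_id(br) if isinstance(br, str) else br
        null_fit, alt_fit = fit_branch_models(
            alignment, tree, bid, global_fit=gfit, omega_cap=omega_cap
        )
        lrt = max(2.0 * (alt_fit.log_likelihood - null_fit.log_likelihood), 0.0)
        out.append(
            BranchTestResult(
                gene_id=gene_id,
                branch_id=bid,
                branch_name=tree.branch_name(bid),
                null_loglik=null_fit.log_likelihood,
                alt_loglik=alt_fit.log_likelihood,
                lrt=lrt,
                p_value=lrt_pvalue(null_fit.log_likelihood, alt_fit.log_likelihood),
                corrected_p=None,
                omega1=alt_fit.omega1,
                omega2=alt_fit.omega2,
                weight2=alt_fit.weight2,
                background_omega=alt_fit.background_omega,
                omega_capped=alt_fit.omega2 >= omega_cap * (1.0 - 1e-6),
                converged=alt_fit.converged and null_fit.converged,
            )
        )
    return out


def correct_results(
    results: list[BranchTestResult], family: str = "across_genes"
) -> list[BranchTestResult]:
    """Attach Holm-corrected p-values.

    ``across_genes``: one correction family per branch, across genes (the
    default reading of correcting gene-level calls); ``within_gene``: one
    family per gene, across its tested branches."""
    if family not in ("across_genes", "within_gene"):
        raise ValueError("family must be 'across_genes' or 'within_gene'")
    key = (lambda r: r.branch_id) if family == "across_genes" else (lambda r: r.gene_id)
    by_family: dict[object, list[BranchTestResult]] = {}
    for r in results:
        by_family.setdefault(key(r), []).append(r)
    for members in by_family.values():
        corrected = holm_bonferroni([r.p_value for r in members])
        for r, cp in zip(members, corrected):
            r.corrected_p = float(cp)
    return results


@dataclass
class PsgCall:
    gene_id: str
    corrected_p: float
    omega2: float
    weight2: float
    omega_capped: bool
    percent_sites: float = field(init=False)

    def __post_init__(self) -> None:
        self.percent_sites = 100.0 * self.weight2


def call_psgs(
    results: list[BranchTestResult],
    focal_taxon: str,
    alpha: float = DEFAULT_ALPHA,
) -> list[PsgCall]:
    """Positively selected genes: focal-branch corrected p <= alpha and no
    other terminal branch of the gene significant at alpha ('uniquely under
    selection' in the focal lineage).  Non-converged results never produce
    calls."""
    if any(r.corrected_p is None for r in results):
        raise ValueError("results must carry corrected p-values; run correct_results first")
    by_gene: dict[str, list[BranchTestResult]] = {}
    for r in results:
        by_gene.setdefault(r.gene_id, []).append(r)
    calls = []
    for gene_id, rs in sorted(by_gene.items()):
        focal = [r for r in rs if r.branch_name == focal_taxon]
        if not focal:
            continue
        f = focal[0]
        others = [r for r in rs if r.branch_name != focal_taxon]
        if (
            f.converged
            and f.corrected_p <= alpha
            and all(r.corrected_p > alpha for r in others)
        ):
            calls.append(
                PsgCall(
                    gene_id=gene_id,
                    corrected_p=f.corrected_p,
                    omega2=f.omega2,
                    weight2=f.weight2,
                    omega_capped=f.omega_capped,
                )
            )
    return calls
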