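"""The branch-site likelihood core: closed-form anchors, a brute-force
ancestral-state-enumeration oracle, the chi-square boundary mixture, Holm
correction against the direct step-down formula, and the PSG calling rule."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import chi2

from sawselect.codonalign import CodonAlignment
from sawselect.genetics import CODON_INDEX, N_CODONS, SENSE_CODONS
from sawselect.gy94 import log_likelihood
from sawselect.selection import (
    BranchTestResult,
    call_psgs,
    correct_results,
    fit_branch_models,
    fit_global,
    holm_bonferroni,
    lrt_pvalue,
)
from sawselect.synthetic import (
    CodonModelParams,
    SimulationConfig,
    simulate_codon_alignment,
)
from sawselect.trees import SpeciesTree

# ---------------------------------------------------------------------------
# Independent oracle: GY94 generator built by explicit loops over codon pairs
# and Biopython translation, exponentiated with scipy.linalg.expm, with the
# likelihood summed over every ancestral-state assignment.
# ---------------------------------------------------------------------------


def oracle_rate_matrix(kappa, omega):
    ts_pairs = {frozenset("AG"), frozenset("CT")}
    Q = np.zeros((N_CODONS, N_CODONS))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [(x, y) for x, y in zip(a, b) if x != y]
            if len(diffs) != 1:
                continue
            rate = 1.0 / N_CODONS  # uniform codon frequencies
            if frozenset(diffs[0]) in ts_pairs:
                rate *= kappa
            if str(Seq(a).translate()) != str(Seq(b).translate()):
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def oracle_transition(kappa, omega, t):
    Q = oracle_rate_matrix(kappa, omega)
    mu = -(np.diag(Q) * (1.0 / N_CODONS)).sum()
    return expm(Q * t / mu)


def oracle_loglik_three_taxon(seqs, lengths, kappa, omega):
    """Rooted tree ((A,B),C): enumerate root and internal states."""
    tA, tB, tAB, tC = lengths
    PA = oracle_transition(kappa, omega, tA)
    PB = oracle_transition(kappa, omega, tB)
    PAB = oracle_transition(kappa, omega, tAB)
    PC = oracle_transition(kappa, omega, tC)
    codes = {k: [CODON_INDEX[s[i:i + 3]] for i in range(0, len(s), 3)] for k, s in seqs.items()}
    total = 0.0
    for site in range(len(codes["A"])):
        a, b, c = codes["A"][site], codes["B"][site], codes["C"][site]
        lik = 0.0
        for root, internal in itertools.product(range(N_CODONS), repeat=2):
            lik += (
                (1.0 / N_CODONS)
                * PAB[root, internal] * PA[internal, a] * PB[internal, b]
                * PC[root, c]
            )
        total += np.log(lik)
    return total


class TestLogLikelihood:
    def test_two_tips_zero_branches_closed_form(self):
        tree = SpeciesTree.from_newick("(A:0,B:0);")
        ll = log_likelihood(
            {"A": "ATG", "B": "ATG"}, tree, kappa=2.0, pi=None,
            branch_omegas={b: [(1.0, 1.0)] for b in tree.branch_ids()},
        )
        assert ll == pytest.approx(np.log(1.0 / 61.0), abs=1e-9)

    def test_duplicate_column_doubles_contribution(self):
        tree = SpeciesTree.from_newick("(A:0.1,B:0.2);")
        omegas = {b: [(0.5, 1.0)] for b in tree.branch_ids()}
        one = log_likelihood({"A": "ATG", "B": "ACG"}, tree, 2.0, None, omegas)
        two = log_likelihood({"A": "ATGATG", "B": "ACGACG"}, tree, 2.0, None, omegas)
        assert two == pytest.approx(2 * one, abs=1e-9)

    def test_matches_bruteforce_enumeration(self, rng):
        newick = "((A:0.21,B:0.09):0.13,C:0.33);"
        tree = SpeciesTree.from_newick(newick)
        kappa, omega = 2.3, 0.6
        for _ in range(3):
            n = int(rng.integers(2, 6))
            seqs = {
                k: "".join(SENSE_CODONS[i] for i in rng.integers(0, N_CODONS, n))
                for k in "ABC"
            }
            got = log_likelihood(
                seqs, tree, kappa, None,
                {b: [(omega, 1.0)] for b in tree.branch_ids()},
            )
            want = oracle_loglik_three_taxon(seqs, (0.21, 0.09, 0.13, 0.33), kappa, omega)
            assert got == pytest.approx(want, abs=1e-6)

    def test_mixture_matches_hand_mixed_prunings(self):
        tree = SpeciesTree.from_newick("((A:0.2,B:0.1):0.1,C:0.3);")
        seqs = {"A": "ATGAAA", "B": "ACGAAA", "C": "ATGAGA"}
        test_branch = tree.tip_id("A")
        base = {b: [(0.4, 1.0)] for b in tree.branch_ids()}
        mix = dict(base)
        mix[test_branch] = [(0.2, 0.7), (5.0, 0.3)]
        mixed = log_likelihood(seqs, tree, 2.0, None, mix)
        # hand mixture: per-site average of the two pure assignments, with the
        # test branch's clock normalized by the mixture-average rate
        from sawselect.gy94 import CodonModel, PrunedAlignment

        model = CodonModel(2.0)
        pruned = PrunedAlignment(tree, seqs)
        P = {
            b: model.transition_matrix(0.4, tree.nodes[b].length)
            for b in tree.branch_ids() if b != test_branch
        }
        mats = model.branch_matrices([(0.2, 0.7), (5.0, 0.3)], tree.nodes[test_branch].length)
        site_mix = sum(
            w * pruned.site_pattern_likelihoods({**P, test_branch: Pk}, model.pi)
            for Pk, w in mats
        )
        want = float(pruned.weights @ np.log(site_mix))
        assert mixed == pytest.approx(want, abs=1e-12)

    def test_rerooting_invariance(self):
        # same unrooted tree, root slid along the C-facing branch
        seqs = {"A": "ATGAAAGGG", "B": "ACGAAAGGG", "C": "ATGAGAGGC"}
        t1 = SpeciesTree.from_newick("((A:0.1,B:0.2):0.05,C:0.25);")
        t2 = SpeciesTree.from_newick("((A:0.1,B:0.2):0.20,C:0.10);")
        lls = [
            log_likelihood(seqs, t, 2.0, None, {b: [(0.5, 1.0)] for b in t.branch_ids()})
            for t in (t1, t2)
        ]
        assert lls[0] == pytest.approx(lls[1], abs=1e-6)

    def test_bad_mixture_weights_rejected(self):
        tree = SpeciesTree.from_newick("(A:0.1,B:0.1);")
        with pytest.raises(ValueError, match="sum"):
            log_likelihood(
                {"A": "ATG", "B": "ATG"}, tree, 2.0, None,
                {b: [(1.0, 0.6)] for b in tree.branch_ids()},
            )


class TestFitting:
    def test_alt_loglik_at_least_null(self, five_taxon_tree, small_alignment):
        gfit = fit_global(small_alignment, five_taxon_tree)
        for tip in ("P_pectinata", "L_erinacea"):
            null_fit, alt_fit = fit_branch_models(
                small_alignment, five_taxon_tree, tip, global_fit=gfit
            )
            assert alt_fit.log_likelihood >= null_fit.log_likelihood - 1e-6

    def test_neutral_single_branch_omega_recovery(self):
        # two taxa separated by one expected substitution per codon, omega=1:
        # the fitted genome-wide omega comes back near 1
        tree = SpeciesTree.from_newick("(A:0.5,B:0.5);")
        params = CodonModelParams(
            branch_mixtures={b: [(1.0, 1.0)] for b in tree.branch_ids()}
        )
        aln = simulate_codon_alignment(
            SimulationConfig(tree=tree, params=params, n_sites=2000, seed=11)
        )
        fit = fit_global(aln, tree)
        assert 0.85 <= fit.omega <= 1.15
        total = sum(fit.branch_lengths.values())
        assert 0.8 <= total <= 1.2


class TestLrtPvalue:
    def test_zero_statistic_gives_one(self):
        assert lrt_pvalue(-100.0, -100.0) == 1.0

    def test_mixture_tail_matches_quadrature(self):
        lrt = 8.0
        p = lrt_pvalue(-100.0, -96.0)
        dens = lambda x: 0.5 * chi2.pdf(x, 1) + 0.5 * chi2.pdf(x, 2)  # noqa: E731
        want, _ = quad(dens, lrt, np.inf)
        assert p == pytest.approx(want, abs=1e-8)

    def test_negative_beyond_tolerance_raises(self):
        with pytest.raises(ValueError, match="negative LRT"):
            lrt_pvalue(-100.0, -100.2)


class TestHolmBonferroni:
    def test_hand_stepdown_example(self):
        got = holm_bonferroni([0.01, 0.04, 0.03])
        assert np.allclose(got, [0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2])[0] == pytest.approx(0.2)

    def test_matches_direct_formula_oracle(self, rng):
        def oracle(p):
            m = len(p)
            order = np.argsort(p, kind="stable")
            adj = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, min(1.0, (m - rank) * p[idx]))
                adj[idx] = running
            return adj

        for _ in range(100):
            p = rng.random(int(rng.integers(1, 12)))
            assert np.allclose(holm_bonferroni(p), oracle(p), atol=1e-12)

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            holm_bonferroni([0.5, 1.5])

    def test_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.random(20)
        assert np.allclose(holm_bonferroni(p), multipletests(p, method="holm")[1])


def _result(gene, branch, p, corrected=None):
    return BranchTestResult(
        gene_id=gene, branch_id=hash(branch) % 100, branch_name=branch,
        null_loglik=-10.0, alt_loglik=-9.0, lrt=2.0, p_value=p,
        corrected_p=corrected, omega1=0.2, omega2=2.0, weight2=0.1,
        background_omega=0.2, omega_capped=False,
    )


class TestCallPsgs:
    TIPS = ("L_menadoensis", "C_milii", "S_retifer", "L_erinacea", "P_pectinata")

    def _gene(self, gene, focal_p, other_p):
        return [
            _result(gene, t, focal_p if t == "P_pectinata" else other_p,
                    corrected=focal_p if t == "P_pectinata" else other_p)
            for t in self.TIPS
        ]

    def test_focal_significant_others_not_called(self):
        calls = call_psgs(self._gene("g1", 0.03, 0.4), "P_pectinata")
        assert [c.gene_id for c in calls] == ["g1"]

    def test_not_unique_when_other_branch_significant(self):
        results = self._gene("g1", 0.03, 0.4)
        results[3].corrected_p = 0.01  # L_erinacea also significant
        assert call_psgs(results, "P_pectinata") == []

    def test_alpha_boundary_inclusive(self):
        calls = call_psgs(self._gene("g1", 0.05, 0.9), "P_pectinata")
        assert len(calls) == 1

    def test_uncorrected_results_rejected(self):
        with pytest.raises(ValueError, match="corrected"):
            call_psgs([_result("g1", "P_pectinata", 0.01)], "P_pectinata")

    def test_correct_results_across_genes_per_branch(self):
        results = self._gene("g1", 0.01, 0.5) + self._gene("g2", 0.04, 0.5)
        for r in results:
            r.corrected_p = None
        correct_results(results, family="across_genes")
        focal = sorted(
            (r.gene_id, r.corrected_p) for r in results if r.branch_name == "P_pectinata"
        )
        # Holm over the two focal-branch p-values: (0.01*2, max(0.02, 0.04))
        assert focal[0][1] == pytest.approx(0.02)
        assert focal[1][1] == pytest.approx(0.04)
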