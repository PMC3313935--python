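import numpy as np
import pytest

from oracles import enum_joint_posterior, enum_marginal_posterior, enum_site_likelihood
from submap.exceptions import NumericalError, SubmapError
from submap.inference import (LikelihoodEngine, fit_homogeneous,
                              joint_endpoint_posterior, site_likelihood)
from submap.models import BranchModelMap, build_jc, build_t92, build_yn98
from submap.phylio import Alignment, nucleotide_alphabet, read_newick
from submap.simulate import random_tree, simulate_alignment
from conftest import random_nt_alignment


def _oracle_inputs(tree, aln, model):
    site_ind = {}
    P = {bid: model.transition_matrix(t) for bid, t in tree.branch_lengths().items()}
    return P


def _site_indicators(aln, site):
    return {taxon: aln.indicators()[r, site - 1]
            for r, taxon in enumerate(aln.taxa)}


class TestSiteLikelihood:
    def test_two_leaf_closed_form(self, jc4, nt_alphabet):
        tree = read_newick("(A:0.06,B:0.04);")
        t = 0.1
        same = Alignment.from_sequences(nt_alphabet, [("A", "G"), ("B", "G")])
        diff = Alignment.from_sequences(nt_alphabet, [("A", "G"), ("B", "T")])
        p_same = 0.25 + 0.75 * np.exp(-4 * t / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * t / 3)
        assert site_likelihood(tree, same, jc4, 1) == pytest.approx(np.log(0.25 * p_same))
        assert site_likelihood(tree, diff, jc4, 1) == pytest.approx(np.log(0.25 * p_diff))

    def test_all_ambiguous_site_has_probability_one(self, jc4, tree4, nt_alphabet):
        aln = Alignment.from_sequences(
            nt_alphabet, [("A", "N"), ("B", "-"), ("C", "N"), ("D", "?")])
        assert site_likelihood(tree4, aln, jc4, 1) == pytest.approx(0.0, abs=1e-12)

    def test_pruning_matches_enumeration(self, rng):
        trees = [
            "((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1);",
            "(A:0.2,B:0.1,(C:0.3,(D:0.15,E:0.25):0.1):0.2);",
            "((A:0.4,B:0.02):0.3,C:0.5);",
        ]
        for newick in trees:
            tree = read_newick(newick)
            for model in (build_jc(), build_t92(float(rng.uniform(0.5, 4)),
                                                float(rng.uniform(0.1, 0.9)))):
                aln = random_nt_alignment(rng, tree.leaf_labels, 3)
                P = {bid: model.transition_matrix(t)
                     for bid, t in tree.branch_lengths().items()}
                for site in (1, 2, 3):
                    expected = enum_site_likelihood(
                        tree, _site_indicators(aln, site), P, model.pi)
                    got = site_likelihood(tree, aln, model, site)
                    assert got == pytest.approx(np.log(expected), abs=1e-10)

    def test_impossible_site_flags_minus_inf(self, jc4, nt_alphabet):
        tree = read_newick("(A:0.0,B:0.0);")
        aln = Alignment.from_sequences(nt_alphabet, [("A", "A"), ("B", "C")])
        assert site_likelihood(tree, aln, jc4, 1) == -np.inf

    def test_taxa_mismatch(self, jc4, tree4, nt_alphabet):
        aln = Alignment.from_sequences(nt_alphabet, [("A", "A"), ("B", "C")])
        with pytest.raises(SubmapError, match="mismatch"):
            site_likelihood(tree4, aln, jc4, 1)

    def test_root_placement_invariance(self, jc4, rng):
        # two rooted displays of the same unrooted 4-leaf tree
        displays = [
            "((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1);",
            "(A:0.1,B:0.2,(C:0.12,D:0.3):0.25);",
            "((C:0.12,D:0.3):0.25,A:0.1,B:0.2);",
        ]
        aln = random_nt_alignment(rng, list("ABCD"), 20)
        lls = []
        for d in displays:
            tree = read_newick(d)
            eng = LikelihoodEngine(tree, aln, jc4, compute_outside=False)
            lls.append(eng.total_loglik)
        assert np.ptp(lls) < 1e-8


class TestJointPosterior:
    def test_normalization_every_branch_and_site(self, tree4, aln4, t92_model):
        engine = LikelihoodEngine(tree4, aln4, t92_model)
        for bid in range(1, tree4.n_branches + 1):
            for site in range(1, aln4.n_sites + 1):
                J = engine.joint_posterior(bid, site)
                assert J.sum() == pytest.approx(1.0, abs=1e-10)
                assert J.min() >= 0

    def test_leaf_state_confines_posterior_column(self, tree4, aln4, jc4, nt_alphabet):
        # branch 2 leads to leaf B, observed state at site 1 is 'A'
        engine = LikelihoodEngine(tree4, aln4, jc4)
        node = tree4.branch_node(2)
        assert node.label == "B"
        J = engine.joint_posterior(2, 1)
        observed = nt_alphabet.index[aln4.tokens[aln4.taxa.index("B")][0]]
        assert J[:, observed].sum() == pytest.approx(1.0)

    def test_two_leaf_posterior_concentrates_on_observed_pair(self, jc4, nt_alphabet):
        tree = read_newick("(A:0.1,B:0.1);")
        aln = Alignment.from_sequences(nt_alphabet, [("A", "A"), ("B", "C")])
        J = joint_endpoint_posterior(tree, aln, jc4, 1, 1)
        nz = np.argwhere(J > 1e-12)
        assert len(nz) == 1

    def test_matches_enumeration_including_marginals(self, rng):
        tree = read_newick("(A:0.2,B:0.1,(C:0.3,(D:0.15,E:0.25):0.1):0.2);")
        model = build_t92(2.0, 0.3)
        aln = random_nt_alignment(rng, tree.leaf_labels, 2)
        P = {bid: model.transition_matrix(t)
             for bid, t in tree.branch_lengths().items()}
        engine = LikelihoodEngine(tree, aln, model)
        for site in (1, 2):
            ind = _site_indicators(aln, site)
            for bid in range(1, tree.n_branches + 1):
                expected = enum_joint_posterior(tree, ind, P, model.pi, bid)
                got = engine.joint_posterior(bid, site)
                assert np.max(np.abs(got - expected)) < 1e-10
                # marginalizing over the top state gives the bottom-node marginal
                node = tree.branch_node(bid)
                marg = enum_marginal_posterior(tree, ind, P, model.pi,
                                               node.parent.node_id)
                assert np.max(np.abs(got.sum(axis=1) - marg)) < 1e-10

    def test_zero_likelihood_site_raises(self, jc4, nt_alphabet):
        tree = read_newick("(A:0.0,B:0.0);")
        aln = Alignment.from_sequences(nt_alphabet, [("A", "A"), ("B", "C")])
        with pytest.raises(NumericalError):
            joint_endpoint_posterior(tree, aln, jc4, 1, 1)

    def test_nonhomogeneous_branch_models_used(self, rng):
        tree = read_newick("((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1);")
        aln = random_nt_alignment(rng, list("ABCD"), 5)
        hom = BranchModelMap("t92", {"kappa": 2.0, "theta": 0.5})
        het = BranchModelMap("t92", {"kappa": 2.0, "theta": 0.5},
                             overrides={1: {"theta": 0.95}})
        J_hom = LikelihoodEngine(tree, aln, hom).joint_posterior(1, 1)
        J_het = LikelihoodEngine(tree, aln, het).joint_posterior(1, 1)
        assert not np.allclose(J_hom, J_het)


class TestFitHomogeneous:
    def test_recovers_omega_from_homogeneous_simulation(self):
        tree = random_tree(20, seed=41)
        model = build_yn98(2.0, 0.2)
        aln, _ = simulate_alignment(tree, model, 2000, seed=42)
        fit = fit_homogeneous(tree, aln, "yn98", tol_lnl=1.0)
        assert 0.15 <= fit.params["omega"] <= 0.25
        assert all(b >= a - 1e-9 for a, b in zip(fit.trace, fit.trace[1:]))
        assert fit.converged

    def test_refit_from_truth_converges_immediately(self):
        tree = random_tree(8, seed=7)
        model = build_t92(2.0, 0.7)
        aln, _ = simulate_alignment(tree, model, 500, seed=8)
        first = fit_homogeneous(tree, aln, "t92", tol_lnl=1.0)
        again = fit_homogeneous(first.tree, aln, "t92", tol_lnl=1.0,
                                init=dict(first.params))
        # starting at the optimum, one round suffices
        assert len(again.trace) <= 3
        assert again.loglik >= first.loglik - 1.0

    def test_jc_fits_branch_lengths_only(self):
        tree = random_tree(6, seed=3)
        model = build_jc()
        aln, _ = simulate_alignment(tree, model, 800, seed=4)
        fit = fit_homogeneous(tree, aln, "jc", tol_lnl=1.0)
        assert fit.params.get("codon_single_step", False) is False
        # refitted lengths correlate with the simulating lengths
        truth = np.array(list(tree.branch_lengths().values()))
        est = np.array(list(fit.tree.branch_lengths().values()))
        assert np.corrcoef(truth, est)[0, 1] > 0.8

    def test_invalid_tolerance(self, tree4, aln4):
        with pytest.raises(Exception):
            fit_homogeneous(tree4, aln4, "t92", tol_lnl=0.0)
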