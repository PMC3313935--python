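import numpy as np
import pandas as pd
import pytest

from submap.exceptions import NumericalError, ParameterError
from submap.mapping import (CountsTable, conditional_counts, map_alignment,
                            mc_conditional_counts)
from submap.models import (BranchModelMap, build_jc, build_t92, build_yn98,
                           register_dnds, register_gc, register_total)
from submap.phylio import Alignment, read_newick
from submap.simulate import random_tree, simulate_alignment
from conftest import random_nt_alignment


class TestConditionalCounts:
    def test_short_branch_single_jump_limit(self, jc4, gc_register):
        ker = conditional_counts(jc4, 1e-4, gc_register)
        total = ker.total
        for x in range(4):
            for y in range(4):
                if x == y:
                    assert total[x, y] < 1e-3
                else:
                    assert total[x, y] == pytest.approx(1.0, abs=1e-3)
                    # mass concentrates on the type of the observed change
                    s = gc_register.classify(x, y)
                    si = gc_register.types.index(s)
                    assert ker.counts[x, y, si] == pytest.approx(1.0, abs=1e-3)

    def test_typed_counts_partition_total(self, t92_model, gc_register, nt_alphabet):
        ker_typed = conditional_counts(t92_model, 0.6, gc_register)
        ker_all = conditional_counts(t92_model, 0.6, register_total(nt_alphabet))
        assert np.max(np.abs(ker_typed.total - ker_all.total)) < 1e-10

    def test_uniformization_rate_invariance(self, t92_model, gc_register):
        k1 = conditional_counts(t92_model, 0.4, gc_register, mu_factor=1.0)
        k2 = conditional_counts(t92_model, 0.4, gc_register, mu_factor=2.0)
        assert np.max(np.abs(k1.counts - k2.counts)) < 1e-9

    def test_unconditional_identity(self, rng):
        # sum_{x,y} pi_x P_xy(t) E[N_total | x,y,t] = t for a normalized model
        for _ in range(5):
            model = build_t92(float(rng.uniform(0.5, 5)), float(rng.uniform(0.1, 0.9)))
            t = float(rng.uniform(0.05, 5.0))
            reg = register_gc(model.alphabet)
            ker = conditional_counts(model, t, reg)
            got = float(np.sum(model.pi[:, None] * ker.pxy * ker.total))
            assert got == pytest.approx(t, abs=1e-8)

    def test_invalid_arguments(self, jc4, gc_register):
        with pytest.raises(ParameterError):
            conditional_counts(jc4, 0.0, gc_register)
        with pytest.raises(ParameterError):
            conditional_counts(jc4, 0.5, gc_register, mu_factor=0.5)

    def test_matches_monte_carlo_oracle(self, jc4, gc_register):
        ker = conditional_counts(jc4, 0.5, gc_register)
        for (x, y) in [(0, 0), (0, 2), (1, 3)]:
            mc = mc_conditional_counts(jc4, 0.5, gc_register, x, y, 120_000, seed=5)
            z = (ker.counts[x, y] - mc["mean"]) / np.maximum(mc["se"], 1e-9)
            assert np.max(np.abs(z)) < 4.0


class TestMonteCarloOracle:
    def test_tiny_time_same_endpoint_means_no_jumps(self, jc4, gc_register):
        mc = mc_conditional_counts(jc4, 1e-4, gc_register, 2, 2, 2000, seed=0)
        assert mc["mean"].sum() < 1e-3

    def test_fixed_seed_is_bitwise_reproducible(self, t92_model, gc_register):
        a = mc_conditional_counts(t92_model, 0.3, gc_register, 0, 1, 20_000, seed=11)
        b = mc_conditional_counts(t92_model, 0.3, gc_register, 0, 1, 20_000, seed=11)
        assert np.array_equal(a["mean"], b["mean"])
        assert a["n_accepted"] == b["n_accepted"]

    def test_low_acceptance_raises(self, jc4, gc_register):
        # at t=1e-3 almost no path from A ends in G
        with pytest.raises(NumericalError, match="increase n_paths"):
            mc_conditional_counts(jc4, 1e-3, gc_register, 0, 2, 2000, seed=1)


class TestMapAlignment:
    def test_identical_sequences_short_branches_give_near_zero_counts(
            self, jc4, gc_register, nt_alphabet):
        tree = read_newick("((A:0.02,B:0.03):0.01,C:0.05);")
        aln = Alignment.from_sequences(
            nt_alphabet, [("A", "ACGT" * 5), ("B", "ACGT" * 5), ("C", "ACGT" * 5)])
        counts = map_alignment(tree, aln, jc4, gc_register)
        for bid, total in counts.totals().items():
            assert total < 0.1 * aln.n_sites * tree.branch_lengths()[bid]

    def test_per_site_layer_sums_to_branch_totals(self, t92_model, gc_register, rng):
        tree = random_tree(6, seed=2)
        aln = random_nt_alignment(rng, tree.leaf_labels, 40)
        counts = map_alignment(tree, aln, t92_model, gc_register, per_site=True)
        assert np.allclose(counts.per_site.sum(axis=1), counts.per_branch.values,
                           atol=1e-8)

    def test_grand_total_invariant_to_register(self, t92_model, rng, nt_alphabet):
        tree = random_tree(6, seed=9)
        aln = random_nt_alignment(rng, tree.leaf_labels, 60)
        by_gc = map_alignment(tree, aln, t92_model, register_gc(nt_alphabet))
        by_all = map_alignment(tree, aln, t92_model, register_total(nt_alphabet))
        assert by_gc.grand_total == pytest.approx(by_all.grand_total, abs=1e-8)
        assert np.allclose(by_gc.per_branch.sum(axis=1), by_all.per_branch["all"],
                           atol=1e-8)

    def test_root_placement_invariance_of_counts(self, jc4, gc_register, rng):
        displays = [
            "((A:0.1,B:0.2):0.15,(C:0.12,D:0.3):0.1);",
            "((C:0.12,D:0.3):0.25,A:0.1,B:0.2);",
        ]
        aln = random_nt_alignment(rng, list("ABCD"), 50)
        results = []
        for d in displays:
            tree = read_newick(d)
            counts = map_alignment(tree, aln, jc4, gc_register)
            keyed = {}
            for bid in counts.branch_ids:
                child = counts.branch_children[bid]
                keyed[child if child in "ABCD" else "internal"] = \
                    counts.per_branch.loc[bid].to_numpy()
            results.append(keyed)
        for key in results[0]:
            assert np.allclose(results[0][key], results[1][key], atol=1e-8)

    def test_zero_length_branch_gets_zero_counts(self, jc4, gc_register, nt_alphabet):
        tree = read_newick("((A:0.0,B:0.2):0.1,C:0.3);")
        aln = Alignment.from_sequences(
            nt_alphabet, [("A", "ACG"), ("B", "ACG"), ("C", "ACG")])
        counts = map_alignment(tree, aln, jc4, gc_register)
        bid_a = next(b for b in counts.branch_ids if counts.branch_children[b] == "A")
        assert counts.per_branch.loc[bid_a].sum() == 0.0

    def test_register_alphabet_mismatch(self, jc4, tree4, aln4, codon61):
        with pytest.raises(ParameterError):
            map_alignment(tree4, aln4, jc4, register_dnds(codon61))

    def test_mapped_totals_match_simulated_truth(self):
        """Pooled over replicates, posterior expected counts are unbiased for
        the true typed counts generated along the simulated paths."""
        model = build_yn98(2.0, 0.2)
        reg = register_dnds(model.alphabet)
        tree = random_tree(10, seed=31)
        diffs = []
        for rep in range(12):
            aln, truth = simulate_alignment(tree, model, 300, seed=1000 + rep,
                                            register=reg)
            counts = map_alignment(tree, aln, model, reg)
            diffs.append(counts.per_branch.sum(axis=0).to_numpy()
                         - truth.counts.sum(axis=0).to_numpy())
        diffs = np.array(diffs)  # (reps, 2)
        mean = diffs.mean(axis=0)
        sem = diffs.std(axis=0, ddof=1) / np.sqrt(len(diffs))
        assert np.all(np.abs(mean) <= 3.5 * sem + 1e-9)


class TestCountsTableIO:
    def test_tsv_round_trip(self, t92_model, gc_register, rng, tmp_path):
        tree = random_tree(5, seed=4)
        aln = random_nt_alignment(rng, tree.leaf_labels, 30)
        counts = map_alignment(tree, aln, t92_model, gc_register)
        path = tmp_path / "counts.tsv"
        counts.to_tsv(path)
        back = CountsTable.from_tsv(path)
        assert back.types == counts.types
        assert np.allclose(back.per_branch.values, counts.per_branch.values)
        assert back.metadata["model"] == "t92"
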