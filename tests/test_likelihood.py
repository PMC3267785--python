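"""Pruning likelihood, numerical scaling, and optimization."""

import numpy as np
import pytest

from bigtree.alignment import Alignment, compress_patterns
from bigtree.enumeration import enumerate_loglik
from bigtree.likelihood import (EPS, INV_EPS, GammaEngine,
                                LikelihoodUnderflowError, apply_scaling,
                                optimize_model, tree_loglik)
from bigtree.model import gamma_discretize, jc_params
from bigtree.simulate import (DEFAULT_GTR, caterpillar_tree,
                              simulate_alignment, simulate_tree)
from bigtree.tree import parse_newick

from _oracles import mp_tree_loglik
from conftest import make_instance


class TestBasics:
    def test_uniform_column_scores_stationary_frequency(self, gtr):
        tree = parse_newick("((A:0,B:0):0,C:0);")
        p = compress_patterns(Alignment(["A", "B", "C"], ["A", "A", "A"]))
        lnl = tree_loglik(tree, p, gtr, gamma_discretize(1.0, 4))
        assert lnl == pytest.approx(np.log(gtr.pi[0]), abs=1e-6)

    def test_all_gap_column_contributes_zero(self, gtr, gamma4):
        tree = parse_newick("((A:0.1,B:0.2):0.1,C:0.3);")
        base = compress_patterns(Alignment(["A", "B", "C"], ["AG", "AT", "AC"]))
        plus = compress_patterns(Alignment(["A", "B", "C"], ["AG-", "AT-", "AC-"]))
        a = tree_loglik(tree, base, gtr, gamma4)
        b = tree_loglik(tree, plus, gtr, gamma4)
        assert b == pytest.approx(a, abs=1e-9)

    def test_pattern_weight_linearity(self, gtr, gamma4, small_instance):
        tree, _, paln = small_instance
        engine = GammaEngine(tree, paln, gtr, gamma4)
        site = engine.site_logl()
        w = paln.weights.astype(float)
        bumped = w.copy()
        bumped[3] += 1.0
        assert np.dot(bumped, site) - np.dot(w, site) == \
            pytest.approx(site[3], abs=1e-9)

    def test_missing_taxon_rejected(self, gtr, gamma4):
        tree = simulate_tree(5, 1)
        aln = Alignment(["X", "Y", "Z"], ["A", "C", "G"])
        with pytest.raises(ValueError, match="missing from alignment"):
            GammaEngine(tree, compress_patterns(aln), gtr, gamma4)


class TestRootInvariance:
    @pytest.mark.parametrize("seed", range(3))
    def test_rerooting_leaves_lnl_unchanged(self, gtr, gamma4, seed):
        tree, _, paln = make_instance(12, 100, seed=seed, gappyness=0.3)
        engine = GammaEngine(tree, paln, gtr, gamma4)
        values = [engine.loglik((u, v)) for u, v, _ in tree.edges()[:5]]
        ref = values[0]
        for v in values[1:]:
            assert v == pytest.approx(ref, rel=1e-10)


class TestEnumerationOracle:
    @pytest.mark.parametrize("n,seed", [(4, 0), (5, 1), (5, 2), (6, 3), (6, 4)])
    def test_small_trees_match_exhaustive_sum(self, gtr, n, seed):
        tree = simulate_tree(n, seed, mean_branch_length=0.3)
        aln = simulate_alignment(tree, gtr, 0.8, 10, seed + 50)
        paln = compress_patterns(aln)
        for K in (1, 4):
            g = gamma_discretize(0.8, K)
            a = GammaEngine(tree, paln, gtr, g).loglik()
            b = enumerate_loglik(tree, paln, gtr, g)
            assert a == pytest.approx(b, rel=1e-10)


class TestScaling:
    def test_threshold_not_met_leaves_vector_unchanged(self):
        L = np.full((2, 4, 4), 0.5)
        U = np.zeros(2, dtype=np.int64)
        L2, U2 = apply_scaling(L, U)
        assert np.array_equal(L2, L) and np.array_equal(U2, U)

    def test_forced_scaling_multiplies_by_2_pow_256(self):
        L = np.full((1, 4, 4), 2.0 ** -300)
        U = np.zeros(1, dtype=np.int64)
        L2, U2 = apply_scaling(L, U)
        assert np.all(L2 == 2.0 ** -44)
        assert U2[0] == 1

    def test_mixed_patterns_scaled_independently(self):
        L = np.ones((2, 4, 4))
        L[1] = 2.0 ** -300
        U = np.zeros(2, dtype=np.int64)
        L2, U2 = apply_scaling(L, U)
        assert np.all(L2[0] == 1.0) and U2[0] == 0
        assert np.all(L2[1] == 2.0 ** -44) and U2[1] == 1

    def test_largest_to_one_policy_agrees_with_threshold_policy(self, gtr):
        tree = caterpillar_tree(120, 0.3)
        aln = simulate_alignment(tree, gtr, 0.6, 10, 4)
        paln = compress_patterns(aln)
        g = gamma_discretize(0.6, 4)
        a = GammaEngine(tree, paln, gtr, g).loglik()
        b = GammaEngine(tree, paln, gtr, g,
                        scaling_policy="largest-to-one").loglik()
        assert b == pytest.approx(a, rel=1e-12)

    def test_deep_caterpillar_matches_extended_precision_oracle(self, gtr):
        tree = caterpillar_tree(200, 0.25)
        aln = simulate_alignment(tree, gtr, 0.6, 8, 3)
        paln = compress_patterns(aln)
        g = gamma_discretize(0.6, 4)
        engine = GammaEngine(tree, paln, gtr, g)
        i, j = engine.default_root_edge()
        _, U = engine.conditional(j, i)
        assert U.max() >= 1  # scaling actually engaged
        scaled = engine.loglik()
        oracle = mp_tree_loglik(tree, paln, gtr, g)
        assert scaled == pytest.approx(oracle, rel=1e-8)


class TestBranchOptimization:
    def test_single_branch_matches_golden_section_scan(self, gtr, gamma4):
        tree, _, paln = make_instance(8, 150, seed=4)
        u, v, _ = tree.edges()[3]

        def lnl_at(b):
            tree.set_branch_length(u, v, b)
            return GammaEngine(tree, paln, gtr, gamma4).loglik()

        # golden-section scan oracle on [1e-8, 10]
        import math
        phi = (math.sqrt(5) - 1) / 2
        a, b = math.log(1e-8), math.log(10.0)
        c, d = b - phi * (b - a), a + phi * (b - a)
        fc, fd = lnl_at(math.exp(c)), lnl_at(math.exp(d))
        for _ in range(60):
            if fc >= fd:
                b, d, fd = d, c, fc
                c = b - phi * (b - a)
                fc = lnl_at(math.exp(c))
            else:
                a, c, fc = c, d, fd
                d = a + phi * (b - a)
                fd = lnl_at(math.exp(d))
        oracle = math.exp((a + b) / 2)

        engine = GammaEngine(tree, paln, gtr, gamma4)
        pair = engine.edge_vectors()[(u, v)]
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(lambda x: -engine.edge_loglik(pair, x),
                              bounds=(1e-8, 10.0), method="bounded",
                              options={"xatol": 1e-8})
        assert res.x == pytest.approx(oracle, abs=1e-4)

    def test_identical_sequences_drive_branch_to_minimum(self, gtr, gamma4):
        aln = Alignment(["A", "B", "C"],
                        ["ACGTACGTACGTACGTACGT", "ACGTACGTACGTACGTACGT",
                         "GTCAGTCAGTCAGGGGACCA"])
        tree = parse_newick("((A:0.1,B:0.1):0.1,C:0.5);")
        paln = compress_patterns(aln)
        engine = GammaEngine(tree, paln, gtr, gamma4)
        engine.optimize_branch_lengths(tol=0.001)
        a = tree.node_of_taxon["A"]
        b = tree.node_of_taxon["B"]
        inner = next(iter(tree.adj[a]))
        assert tree.adj[a][inner] + tree.adj[b][inner] < 1e-4

    def test_monotone_and_fixed_point(self, gtr, gamma4, small_instance):
        tree, _, paln = small_instance
        engine = GammaEngine(tree, paln, gtr, gamma4)
        before = engine.loglik()
        first = engine.optimize_branch_lengths(tol=0.01)
        assert first >= before
        again = engine.optimize_branch_lengths(tol=0.01)
        assert again >= first - 1e-9
        assert again - first < 0.01


class TestModelOptimization:
    def test_jc_data_recovers_flat_exchangeabilities(self):
        jc = jc_params()
        tree = simulate_tree(8, 6, mean_branch_length=0.15)
        aln = simulate_alignment(tree, jc, None, 10000, 7)
        paln = compress_patterns(aln)
        params, _ = optimize_model(tree, paln, jc, 1.0, tol=0.05,
                                   max_rounds=2)
        for rate in params.exchangeabilities:
            assert 0.8 <= rate <= 1.2

    def test_alpha_recovery(self, gtr):
        tree = simulate_tree(32, 8, mean_branch_length=0.1)
        aln = simulate_alignment(tree, gtr, 0.5, 4000, 9)
        paln = compress_patterns(aln)
        GammaEngine(tree, paln, gtr,
                    gamma_discretize(0.5, 4)).optimize_branch_lengths(tol=0.5)
        _, alpha = optimize_model(tree, paln, gtr, 1.0, tol=0.05,
                                  max_rounds=2)
        assert 0.4 <= alpha <= 0.6

    def test_fixed_point_from_truth(self, gtr, gamma4, small_instance):
        tree, _, paln = small_instance
        base = GammaEngine(tree, paln, gtr, gamma4).loglik()
        params, alpha = optimize_model(tree, paln, gtr, 0.7, tol=0.1,
                                       max_rounds=1)
        after = GammaEngine(tree, paln, params,
                            gamma_discretize(alpha, 4)).loglik()
        assert after >= base - 1e-9
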