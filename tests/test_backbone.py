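"""Backbone construction: innermost node, decomposition, clustering, labels."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import linkage

from bigtree.backbone import (BackboneConfig, BOUNDARY, INSIDE, OUTSIDE,
                              allocate_clusters, assign_clusters,
                              average_linkage, cluster_count,
                              count_backbone_tips, cut_dendrogram,
                              decompose_subtrees, extract_backbone,
                              find_innermost_node, ideal_backbone_size,
                              label_backbone)
from bigtree.likelihood import GammaEngine
from bigtree.simulate import caterpillar_tree, simulate_tree
from bigtree.tree import parse_newick

from _oracles import naive_average_linkage
from conftest import make_instance


class TestInnermostNode:
    def test_three_tip_tree(self):
        t = parse_newick("((A:0.1,B:0.2):0.05,C:0.3);")
        assert find_innermost_node(t) == t.inner_nodes()[0]

    def test_balanced_tree_tie_breaks_to_lowest_id(self):
        t = parse_newick("(((A:1,B:1):1,(C:1,D:1):1):1,"
                         "((E:1,F:1):1,(G:1,H:1):1):1);")
        node = find_innermost_node(t)
        # the central edge's endpoints tie; the lower node id wins
        stl = t.all_directed_subtree_lengths()
        total = t.total_length()
        best = total - max(stl[(node, v)] for v in t.adj[node])
        ties = [u for u in t.inner_nodes()
                if total - max(stl[(u, v)] for v in t.adj[u])
                >= best - 1e-12]
        assert len(ties) >= 2 and node == min(ties)

    @pytest.mark.parametrize("criterion", ["max_remainder", "min_var_stl",
                                           "min_var_tipdist",
                                           "max_min_tipdist"])
    def test_matches_exhaustive_criterion_evaluation(self, criterion):
        t = simulate_tree(50, 3)
        node = find_innermost_node(t, criterion)
        total = t.total_length()

        def key(u):
            stls = [t.subtree_length(u, v) for v in sorted(t.adj[u])]
            tipd = [t.distances_from(u)[x] for x in t.tips()]
            return {
                "max_remainder": -(total - max(stls)),
                "min_var_stl": float(np.var(stls)),
                "min_var_tipdist": float(np.var(tipd)),
                "max_min_tipdist": -min(tipd),
            }[criterion]

        best = min(key(u) for u in t.inner_nodes())
        assert key(node) == pytest.approx(best, abs=1e-12)


class TestDecomposition:
    def test_small_tree_yields_three_subtrees(self):
        t = simulate_tree(12, 1)
        node = find_innermost_node(t)
        roots = decompose_subtrees(t, node, m=1024)
        assert len(roots) == 3
        covered = sorted(x for p, v in roots for x in t.subtree_tips(v, p))
        assert covered == t.tips()

    def test_caterpillar_fine_decomposition(self):
        t = caterpillar_tree(10, 0.1)
        node = find_innermost_node(t)
        roots = decompose_subtrees(t, node, m=2)
        tipsets = [frozenset(t.subtree_tips(v, p)) for p, v in roots]
        assert all(1 <= len(s) <= 2 for s in tipsets)
        union = set().union(*tipsets)
        assert len(union) == 10 and sum(map(len, tipsets)) == 10

    @pytest.mark.parametrize("seed", range(3))
    def test_partition_property(self, seed):
        t = simulate_tree(200, seed)
        roots = decompose_subtrees(t, find_innermost_node(t), m=16)
        sizes = [len(t.subtree_tips(v, p)) for p, v in roots]
        assert all(s <= 16 for s in sizes)
        assert sum(sizes) == 200
        union = set()
        for p, v in roots:
            tips = set(t.subtree_tips(v, p))
            assert not union & tips
            union |= tips


class TestAllocation:
    def test_worked_example(self):
        assert allocate_clusters([30000, 10000], 20000) == [15000, 5000]

    def test_single_matrix_takes_everything(self):
        assert allocate_clusters([123], 77) == [77]

    def test_invalid_budget(self):
        with pytest.raises(ValueError):
            allocate_clusters([10, 10], 25)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 500), min_size=1, max_size=12),
           st.data())
    def test_property_sweep(self, sizes, data):
        n = sum(sizes)
        c = data.draw(st.integers(len(sizes), n))
        ci = allocate_clusters(sizes, c)
        assert sum(ci) == c
        assert all(1 <= x <= s for x, s in zip(ci, sizes))


class TestClustering:
    def test_two_leaves_single_merge(self):
        Z = average_linkage(["a", "b"], np.array([[0.0, 2.5], [2.5, 0.0]]))
        assert Z.shape == (1, 4) and Z[0, 2] == pytest.approx(2.5)

    def test_forced_merge_order(self):
        m = np.array([[0.0, 1.0, 10.0], [1.0, 0.0, 10.0], [10.0, 10.0, 0.0]])
        Z = average_linkage(list("ABC"), m)
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx(10.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_merge_heights_match_naive_reference(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.random((14, 3))
        m = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        Z = average_linkage(list(range(14)), m)
        ref = naive_average_linkage(m)
        assert np.allclose(sorted(Z[:, 2]),
                           sorted(h for _, _, h in ref), atol=1e-10)

    def test_cut_extremes_and_counts(self):
        rng = np.random.default_rng(5)
        m = rng.random((9, 9))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        Z = average_linkage(list(range(9)), m)
        assert len(set(cut_dendrogram(Z, 9, 1))) == 1
        assert len(set(cut_dendrogram(Z, 9, 9))) == 9
        for k in (2, 4, 7):
            assert len(set(cut_dendrogram(Z, 9, k))) == k
        with pytest.raises(ValueError):
            cut_dendrogram(Z, 9, 0)


class TestAssignment:
    def test_sizing_routine(self):
        assert ideal_backbone_size(37831, 0.25) == pytest.approx(9457.75)
        assert cluster_count(37831, 0.25) == 9458
        assert cluster_count(40000, 0.5) == 20000

    def test_r_one_gives_all_singletons(self):
        t = simulate_tree(15, 2)
        clusters = assign_clusters(t, BackboneConfig(1.0))
        assert clusters.c == 15
        assert sorted(clusters.tip_to_cluster.values()) == list(range(15))

    @pytest.mark.parametrize("seed,R,m", [(0, 0.5, 1024), (1, 0.4, 16),
                                          (2, 0.6, 32)])
    def test_every_tip_labeled_and_count_matches(self, seed, R, m):
        t = simulate_tree(100, seed)
        clusters = assign_clusters(t, BackboneConfig(R, m))
        assert clusters.c == cluster_count(100, R)
        assert set(clusters.tip_to_cluster) == set(t.taxa())
        assert len(set(clusters.tip_to_cluster.values())) == clusters.c
        assert sum(clusters.budgets) == clusters.c
        assert all(s <= m for s in clusters.subtree_tip_counts)


class TestLabeling:
    def test_all_singletons_make_full_backbone(self):
        t = simulate_tree(12, 4)
        clusters = assign_clusters(t, BackboneConfig(1.0))
        labels = label_backbone(t, clusters)
        for u in t.adj:
            expected = BOUNDARY if t.is_tip(u) else INSIDE
            assert labels.label[u] == expected
        assert count_backbone_tips(labels) == 12

    def test_monophyletic_cluster_yields_single_virtual_tip(self):
        t = parse_newick("(((A:.1,B:.1):.1,(C:.1,D:.1):.1):.2,"
                         "((E:.1,F:.1):.1,G:.4):.2,H:.5);")
        clusters = assign_clusters(t, BackboneConfig(0.62))  # c = 5
        labels = label_backbone(t, clusters)
        sizes = clusters.cluster_sizes()
        multi = [cid for cid, s in sizes.items() if s > 1]
        assert multi  # at least one non-trivial cluster formed
        # clusters are contiguous cherries here -> exactly c boundary tips
        if all(_is_monophyletic(t, clusters, cid) for cid in multi):
            assert count_backbone_tips(labels) == clusters.c

    def test_non_monophyletic_cluster_splits_into_boundaries(self):
        t = parse_newick("((A:.1,(B:.1,C:.1):.1):.1,"
                         "((D:.1,E:.1):.1,F:.1):.1,G:.3);")
        # force a hand-made conflicting clustering: {A, D, E}, {B, C}, {F}, {G}
        from bigtree.backbone import ClusterAssignment

        tip_map = {"A": 0, "D": 0, "E": 0, "B": 1, "C": 1, "F": 2, "G": 3}
        inner = find_innermost_node(t)
        roots = decompose_subtrees(t, inner, 1024)
        clusters = ClusterAssignment(tip_map, 4, [], roots, [])
        labels = label_backbone(t, clusters)
        boundary_clusters = {}
        for b in labels.boundary_nodes():
            cid = labels.cluster_of.get(b)
            if cid is not None:
                boundary_clusters.setdefault(cid, 0)
                boundary_clusters[cid] += 1
        # cluster 0 is split by the topology -> more than one boundary node
        assert boundary_clusters.get(0, 0) >= 2
        assert count_backbone_tips(labels) >= clusters.c

    @pytest.mark.parametrize("seed,R", [(0, 0.3), (1, 0.5), (2, 0.7)])
    def test_no_inside_outside_edge_and_count_lower_bound(self, seed, R):
        t = simulate_tree(60, seed)
        clusters = assign_clusters(t, BackboneConfig(R, m=16))
        labels = label_backbone(t, clusters)
        for u, v, _ in t.edges():
            assert {labels.label[u], labels.label[v]} != {INSIDE, OUTSIDE}
        assert count_backbone_tips(labels) >= clusters.c


def _is_monophyletic(tree, clusters, cid) -> bool:
    taxa = {t for t, c in clusters.tip_to_cluster.items() if c == cid}
    nodes = [tree.node_of_taxon[t] for t in taxa]
    for u, v, _ in tree.edges():
        for a, b in ((u, v), (v, u)):
            side = {tree.taxon_of[x] for x in tree.subtree_tips(b, a)}
            if side == taxa:
                return True
    return False


class TestExtraction:
    @pytest.mark.parametrize("seed,R", [(0, 0.4), (1, 0.6)])
    def test_comprehensive_lnl_through_virtual_tips(self, gtr, gamma4,
                                                    seed, R):
        tree, _, paln = make_instance(40, 250, seed=seed, gappyness=0.3)
        clusters = assign_clusters(tree, BackboneConfig(R, m=16))
        labels = label_backbone(tree, clusters)
        engine = GammaEngine(tree, paln, gtr, gamma4)
        bt, leaf_data = extract_backbone(tree, labels, engine)
        reduced = GammaEngine(bt, paln, gtr, gamma4, leaf_data=leaf_data)
        assert reduced.loglik() == pytest.approx(engine.loglik(), rel=1e-10)
        # backbone is smaller than the comprehensive tree (R < 1)
        assert len(bt.adj) < len(tree.adj)

    def test_full_backbone_is_identity(self, gtr, gamma4, small_instance):
        tree, _, paln = small_instance
        clusters = assign_clusters(tree, BackboneConfig(1.0))
        labels = label_backbone(tree, clusters)
        engine = GammaEngine(tree, paln, gtr, gamma4)
        bt, leaf_data = extract_backbone(tree, labels, engine)
        assert not leaf_data  # all boundary nodes are real tips
        assert GammaEngine(bt, paln, gtr, gamma4).loglik() == engine.loglik()
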