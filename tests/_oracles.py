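"""Independent oracles used by the test suite.

These deliberately avoid the package's pruning/eigendecomposition code
paths: arbitrary-precision pruning via mpmath, naive average-linkage
clustering, graph shortest paths via networkx, and brute-force
enumerations written directly from the definitions.
"""

from __future__ import annotations

import itertools

import mpmath as mp
import numpy as np


def mp_tree_loglik(tree, paln, params, gamma, dps: int = 60,
                   min_branch: float = 1e-8) -> float:
    """Arbitrary-precision unscaled GTR+Gamma log likelihood.

    Straight post-order recursion in mpmath (no numerical scaling is ever
    needed: mpmath floats have an unbounded exponent range).
    """
    mp.mp.dps = dps
    K = gamma.K
    pi = [mp.mpf(x) for x in params.frequencies]
    Qm = mp.matrix(params.generator().tolist())
    pcache: dict[float, mp.matrix] = {}

    def P(b: float, r: float) -> mp.matrix:
        key = b * r
        if key not in pcache:
            pcache[key] = mp.expm(Qm * key)
        return pcache[key]

    n_pat = paln.n_patterns

    def cond(root: int, exclude: int):
        vecs = {}
        for u, parent in tree.postorder_from(root, exclude=exclude):
            p = parent if parent is not None else exclude
            if tree.is_tip(u):
                tv = paln.tip_vectors(tree.taxon_of[u])
                vecs[u] = [[[mp.mpf(tv[c, s]) for s in range(4)]
                            for _ in range(K)] for c in range(n_pat)]
            else:
                kids = [v for v in sorted(tree.adj[u]) if v != p]
                parts = []
                for v in kids:
                    b = max(tree.adj[u][v], min_branch)
                    parts.append((vecs[v], [P(b, rk) for rk in gamma.rates]))
                    del vecs[v]
                out = []
                for c in range(n_pat):
                    row = []
                    for k in range(K):
                        vals = []
                        for a in range(4):
                            prod = mp.mpf(1)
                            for (child, Pk) in parts:
                                s = mp.mpf(0)
                                for bb in range(4):
                                    s += Pk[k][a, bb] * child[c][k][bb]
                                prod *= s
                            vals.append(prod)
                        row.append(vals)
                    out.append(row)
                vecs[u] = out
        return vecs[root]

    tip = tree.node_of_taxon[min(tree.node_of_taxon)]
    i, j = tip, next(iter(tree.adj[tip]))
    Li = cond(i, j)
    Lj = cond(j, i)
    b = max(tree.adj[i][j], min_branch)
    Pk = [P(b, rk) for rk in gamma.rates]
    total = mp.mpf(0)
    for c in range(n_pat):
        l = mp.mpf(0)
        for k in range(K):
            for R in range(4):
                s = mp.mpf(0)
                for S in range(4):
                    s += Pk[k][R, S] * Lj[c][k][S]
                l += pi[R] * Li[c][k][R] * s / K
        total += int(paln.weights[c]) * mp.log(l)
    return float(total)


def naive_average_linkage(matrix: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """O(n^3) unweighted average-linkage clustering from the definition.

    Returns the merge list as (cluster_a, cluster_b, height) with clusters
    as frozensets of leaf indices.
    """
    n = matrix.shape[0]
    clusters: list[frozenset] = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([matrix[a, b] for a in clusters[i]
                             for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        merges.append((clusters[i], clusters[j], d))
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


def brute_force_bipartitions(tree) -> set[frozenset]:
    """Non-trivial bipartitions by splitting on every inner edge, written
    directly against the adjacency structure."""
    taxa = set(tree.taxa())
    ref = min(taxa)
    parts = set()
    for u, v, _ in tree.edges():
        if tree.is_tip(u) or tree.is_tip(v):
            continue
        side = set()
        stack = [(v, u)]
        while stack:
            x, p = stack.pop()
            if tree.is_tip(x):
                side.add(tree.taxon_of[x])
            for y in tree.adj[x]:
                if y != p:
                    stack.append((y, x))
        side = frozenset(side if ref not in side else taxa - side)
        parts.add(side)
    return parts


def fitch_oracle(tree, paln) -> int:
    """Exhaustive minimum-change count: minimize over all joint inner-node
    state assignments; a tip edge costs 0 iff the parent state is in the
    tip's allowed set."""
    inner = tree.inner_nodes()
    tips = tree.tips()
    masks = {u: paln.tip_masks(tree.taxon_of[u]) for u in tips}
    total = 0
    weights = paln.weights
    for c in range(paln.n_patterns):
        best = None
        for assign in itertools.product(range(4), repeat=len(inner)):
            state = dict(zip(inner, assign))
            changes = 0
            for u, v, _ in tree.edges():
                if tree.is_tip(u):
                    u, v = v, u
                if tree.is_tip(v):
                    if not (masks[v][c] >> state[u]) & 1:
                        changes += 1
                else:
                    changes += state[u] != state[v]
            if best is None or changes < best:
                best = changes
        total += int(weights[c]) * best
    return total
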