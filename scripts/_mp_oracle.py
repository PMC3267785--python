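"""Arbitrary-precision likelihood oracle (mpmath) for the acceptance script.

Deliberately avoids the package's pruning/eigendecomposition code paths.
"""

from __future__ import annotations

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


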