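"""Exhaustive small-instance likelihood by ancestral-state enumeration.

The site likelihood is computed as an explicit sum over all 4^(n-2) joint
ancestral state assignments (times rate categories), with transition
probabilities from `scipy.linalg.expm` — deliberately sharing no code
with the pruning recursion or the eigendecomposition, so it can serve as
an independent check for trees with up to ~6 tips.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from .alignment import MASK_TO_VECTOR, PatternAlignment
from .model import GammaRates, GTRParams
from .tree import Tree

__all__ = ["enumerate_site_likelihoods", "enumerate_loglik",
           "enumerate_loglik_per_site_rates"]


def _edge_list(tree: Tree, root: int):
    order = tree.postorder_from(root)
    return [(parent, u, tree.adj[parent][u]) for u, parent in order
            if parent is not None]


def enumerate_site_likelihoods(tree: Tree, paln: PatternAlignment,
                               params: GTRParams, rates, rate_weights
                               ) -> np.ndarray:
    """(patterns,) site likelihoods summed over rates and all joint
    ancestral state assignments."""
    Q = params.generator()
    pi = params.pi
    root = tree.inner_nodes()[0]
    inner = tree.inner_nodes()
    edges = _edge_list(tree, root)
    P_pat = paln.n_patterns
    out = np.zeros(P_pat)
    tip_vec = {u: MASK_TO_VECTOR[paln.tip_masks(tree.taxon_of[u])]
               for u in tree.tips()}
    for rate, rw in zip(rates, rate_weights):
        P_edge = {(a, b): expm(Q * bl * max(rate, 0.0))
                  for a, b, bl in edges}
        for assign in itertools.product(range(4), repeat=len(inner)):
            state = dict(zip(inner, assign))
            term = np.full(P_pat, pi[state[root]])
            for a, b, bl in edges:
                if tree.is_tip(b):
                    term = term * (tip_vec[b] @ P_edge[(a, b)][state[a]])
                else:
                    term = term * P_edge[(a, b)][state[a], state[b]]
            out += rw * term
    return out


def enumerate_loglik(tree: Tree, paln: PatternAlignment, params: GTRParams,
                     gamma: GammaRates) -> float:
    """Total log likelihood under GTR+Gamma by exhaustive enumeration."""
    K = gamma.K
    site = enumerate_site_likelihoods(tree, paln, params, gamma.rates,
                                      [1.0 / K] * K)
    return float(np.dot(np.asarray(paln.weights, dtype=float), np.log(site)))


def enumerate_loglik_per_site_rates(tree: Tree, paln: PatternAlignment,
                                    params: GTRParams,
                                    pattern_rates: np.ndarray) -> float:
    """Exhaustive log likelihood with one fixed rate per pattern."""
    total = 0.0
    w = np.asarray(paln.weights, dtype=float)
    for p, rate in enumerate(pattern_rates):
        sub = PatternAlignment(list(paln.taxa), paln.patterns[:, [p]],
                               np.array([1]), np.array([0]))
        site = enumerate_site_likelihoods(tree, sub, params, [rate], [1.0])
        total += w[p] * float(np.log(site[0]))
    return total
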