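"""Tree search: parsimony starting trees, lazy SPR, backbone-restricted search.

The full protocol: build a randomized stepwise-addition parsimony tree,
optimize model parameters and branch lengths on the comprehensive tree,
then iterate SPR cycles.  With a reduction factor R < 1 each cycle first
rebuilds the backbone of the current best tree; SPR moves prune and
regraft only within the backbone, but the score driving every acceptance
is the log likelihood of the *comprehensive* tree, evaluated through the
virtual-tip conditional vectors.  After each cycle all branch lengths of
the comprehensive tree (including branches outside the backbone) are
re-optimized and the backbone is rebuilt; the search stops when a cycle
improves the score by less than `tol`.

Candidate reinsertions are scored lazily: the pruned subtree's conditional
vector is combined with the per-edge conditional vectors of the remainder
tree, adjusting only the three branches local to the junction (the split
insertion branch and the subtree's attachment branch), so each candidate
costs O(patterns) instead of a full traversal.  The best improving
candidate per prune is then verified with a full evaluation and accepted
only if the comprehensive score actually increases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment, PatternAlignment, compress_patterns
from .backbone import BackboneConfig, assign_clusters, count_backbone_tips, \
    extract_backbone, induced_subtree, label_backbone
from .likelihood import GammaEngine, optimize_model
from .model import GTRParams, gamma_discretize
from .tree import Tree

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "fitch_score",
    "parsimony_starting_tree",
    "spr_prune",
    "spr_regraft",
    "spr_cycle",
    "backbone_search",
    "evaluate_final",
]

logger = logging.getLogger(__name__)


@dataclass
class SearchConfig:
    """Reproducible search settings; identical config + inputs give an
    identical final tree."""

    seed: int = 1
    R: float = 1.0  # 1.0 = full search, < 1 engages the backbone
    spr_radius: int = 10
    tol: float = 0.5  # log-units per cycle below which the search stops
    max_cycles: int = 8
    m: int = 1024
    model: str = "gamma"  # 'gamma' or 'cat'
    gamma_K: int = 4
    cat_K: int = 25
    optimize_model_params: bool = True
    branch_tol: float = 0.1
    start_branch_length: float = 0.1


@dataclass
class SearchTrace:
    cycle_lnl: list[float] = field(default_factory=list)
    backbone_tips: list[int] = field(default_factory=list)
    accepted_moves: list[int] = field(default_factory=list)
    final_lnl: float = float("-inf")
    params: GTRParams | None = None
    alpha: float | None = None


# ---------------------------------------------------------------------------
# parsimony


def fitch_score(tree: Tree, paln: PatternAlignment | Alignment) -> int:
    """Minimum number of state changes under Fitch counting; gaps and
    ambiguity codes act as their compatible state sets."""
    if isinstance(paln, Alignment):
        paln = compress_patterns(paln)
    i, j = _root_edge(tree)
    mi = _fitch_states(tree, paln, i, j)
    mj = _fitch_states(tree, paln, j, i)
    changes = np.zeros(paln.n_patterns, dtype=np.int64)
    _fitch_fold(tree, paln, i, j, changes)
    _fitch_fold(tree, paln, j, i, changes)
    changes += (mi & mj) == 0
    return int(np.dot(paln.weights, changes))


def _root_edge(tree: Tree) -> tuple[int, int]:
    tip = tree.node_of_taxon[min(tree.node_of_taxon)]
    return tip, next(iter(tree.adj[tip]))


def _fitch_states(tree: Tree, paln: PatternAlignment, root: int, exclude: int
                  ) -> np.ndarray:
    state: dict[int, np.ndarray] = {}
    for u, parent in tree.postorder_from(root, exclude=exclude):
        p = parent if parent is not None else exclude
        if tree.is_tip(u):
            state[u] = paln.tip_masks(tree.taxon_of[u])
        else:
            kids = [v for v in sorted(tree.adj[u]) if v != p]
            a, b = state[kids[0]], state[kids[1]]
            inter = a & b
            state[u] = np.where(inter == 0, a | b, inter)
    return state[root]


def _fitch_fold(tree: Tree, paln: PatternAlignment, root: int, exclude: int,
                changes: np.ndarray) -> None:
    state: dict[int, np.ndarray] = {}
    for u, parent in tree.postorder_from(root, exclude=exclude):
        p = parent if parent is not None else exclude
        if tree.is_tip(u):
            state[u] = paln.tip_masks(tree.taxon_of[u])
        else:
            kids = [v for v in sorted(tree.adj[u]) if v != p]
            a, b = state[kids[0]], state[kids[1]]
            inter = a & b
            empty = inter == 0
            changes += empty
            state[u] = np.where(empty, a | b, inter)


def parsimony_starting_tree(paln: PatternAlignment | Alignment, seed: int,
                            branch_length: float = 0.1) -> Tree:
    """Randomized stepwise-addition parsimony tree.

    The taxon addition order is shuffled by `seed`; each taxon is inserted
    on the branch minimizing the Fitch score (ties: first branch in the
    deterministic edge enumeration).  All branch lengths are set to the
    default before the first likelihood-based optimization.
    """
    if isinstance(paln, Alignment):
        paln = compress_patterns(paln)
    taxa = sorted(paln.taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    tree = Tree()
    center = tree.new_node()
    for taxon in order[:3]:
        tree.add_edge(center, tree.new_node(taxon), branch_length)
    for taxon in order[3:]:
        best_edge, best_score = None, None
        for u, v, _ in tree.edges():
            work = tree.copy()
            _attach_tip(work, u, v, taxon, branch_length)
            score = fitch_score(work, paln)
            if best_score is None or score < best_score:
                best_edge, best_score = (u, v), score
        _attach_tip(tree, best_edge[0], best_edge[1], taxon, branch_length)
    tree.validate()
    return tree


def _attach_tip(tree: Tree, u: int, v: int, taxon: str, bl: float) -> None:
    tree.remove_edge(u, v)
    mid = tree.new_node()
    tree.add_edge(u, mid, bl)
    tree.add_edge(mid, v, bl)
    tree.add_edge(mid, tree.new_node(taxon), bl)


# ---------------------------------------------------------------------------
# SPR primitives


def spr_prune(tree: Tree, p: int, v: int) -> tuple[int, int, float, float, float]:
    """Detach the subtree on the v side of edge (p, v).

    p must be an inner node; its two other neighbors a, b are joined by an
    edge of summed length.  The handle edge (p, v) is kept so the subtree
    can be regrafted.  Returns (a, b, b_pa, b_pb, b_pv) for undo.
    """
    others = [w for w in tree.adj[p] if w != v]
    if len(others) != 2:
        raise ValueError(f"prune point {p} is not a degree-3 junction")
    a, b = others
    ba, bb = tree.adj[p][a], tree.adj[p][b]
    bv = tree.adj[p][v]
    tree.remove_edge(p, a)
    tree.remove_edge(p, b)
    tree.add_edge(a, b, ba + bb)
    return a, b, ba, bb, bv


def spr_regraft(tree: Tree, p: int, v: int, x: int, y: int) -> None:
    """Reinsert the pruned handle (p, v) into edge (x, y), splitting that
    branch halfway (lazy local adjustment)."""
    bxy = tree.adj[x][y]
    tree.remove_edge(x, y)
    tree.add_edge(x, p, bxy / 2.0)
    tree.add_edge(p, y, bxy / 2.0)


def _junction_loglik(engine, VA, ba: float, VB, bb: float, VS, bs: float
                     ) -> float:
    """Score of inserting a subtree (vector VS over branch bs) into an
    edge whose two sides are VA and VB, split into ba + bb."""
    V1 = engine._combine(VA, ba, VB, bb)
    site = engine._root_site_logl(V1, VS, bs)
    return float(np.dot(engine.weights, site))


# ---------------------------------------------------------------------------
# SPR cycle


def spr_cycle(tree: Tree, make_engine, radius: int = 10,
              min_gain: float = 1e-6, lazy_slack: float = 3.0
              ) -> tuple[float, int]:
    """One cycle of lazy SPR over all prune candidates of `tree`.

    `tree` is mutated in place; `make_engine(tree)` must build a pruning
    engine bound to it (with virtual-tip leaf data when `tree` is a
    backbone).  Every candidate reinsertion within `radius` edges of the
    prune point is scored lazily; the best improving move per prune is
    verified with a full evaluation and accepted only if the score
    strictly increases, so the returned score never decreases.
    """
    engine = make_engine(tree)
    current = engine.loglik()
    accepted = 0
    candidates = [(p, v) for p, v, _ in tree.edges() if not _leafish(tree, p)]
    candidates += [(v, p) for p, v, _ in tree.edges() if not _leafish(tree, v)]
    for p, v in sorted(candidates):
        if (p not in tree.adj or v not in tree.adj.get(p, {})):
            continue  # stale candidate after an accepted move
        if len(tree.adj) <= 4:
            break
        subtree_nodes = set(_collect(tree, v, p))
        work = tree.copy()
        a, b, *_ = spr_prune(work, p, v)
        remainder = induced_subtree(work, set(work.adj) - subtree_nodes - {p})
        if sum(1 for u in remainder.adj if len(remainder.adj[u]) == 1) < 3:
            continue
        engine = make_engine(tree)
        VS = engine.conditional(v, p)
        bs = tree.adj[p][v]
        rem_engine = make_engine(remainder)
        vectors = rem_engine.edge_vectors()
        near = _edges_within_radius(remainder, (a, b), radius)
        # reinserting into the joined edge recreates the same topology
        near = [e for e in near if set(e) != {a, b}]
        best_score, best_edge = -np.inf, None
        for (x, y) in near:
            bxy = remainder.adj[x][y]
            VA, VB = vectors[(x, y)]
            score = _junction_loglik(rem_engine, VA, bxy / 2.0, VB, bxy / 2.0,
                                     VS, bs)
            if score > best_score:
                best_score, best_edge = score, (x, y)
        # lazy scores underestimate (no local re-optimization); verify the
        # best candidate unless it is hopelessly below the current score
        if best_edge is None or best_score < current - lazy_slack:
            continue
        snapshot = tree.copy()
        spr_prune(tree, p, v)
        spr_regraft(tree, p, v, *best_edge)
        _optimize_local_branches(
            make_engine(tree), [(best_edge[0], p), (p, best_edge[1]), (p, v)])
        new = make_engine(tree).loglik()
        if new > current:
            current = new
            accepted += 1
        else:
            tree.adj = snapshot.adj
            tree.taxon_of = snapshot.taxon_of
            tree.node_of_taxon = snapshot.node_of_taxon
    return current, accepted


def _optimize_local_branches(engine, edges) -> None:
    """Brent-optimize the given branches of the engine's tree (the three
    branches adjacent to a fresh SPR junction)."""
    from scipy.optimize import minimize_scalar

    from .likelihood import MAX_BRANCH

    tree = engine.tree
    for u, v in edges:
        vectors = engine.edge_vectors()
        pair = vectors[(u, v)]
        res = minimize_scalar(lambda b: -engine.edge_loglik(pair, b),
                              bounds=(engine.min_branch, MAX_BRANCH),
                              method="bounded", options={"xatol": 1e-5})
        tree.set_branch_length(u, v, float(res.x))


def _leafish(tree: Tree, u: int) -> bool:
    return len(tree.adj[u]) == 1


def _leafish_excluding(tree: Tree, u: int, removed: set[int]) -> bool:
    return len([w for w in tree.adj[u] if w not in removed]) == 1


def _collect(tree: Tree, root: int, block: int) -> list[int]:
    out = []
    stack = [(root, block)]
    while stack:
        u, p = stack.pop()
        out.append(u)
        for w in tree.adj[u]:
            if w != p:
                stack.append((w, u))
    return out


def _edges_within_radius(tree: Tree, origin_edge: tuple[int, int],
                         radius: int) -> list[tuple[int, int]]:
    """Edges whose nearer endpoint is within `radius` edges of the origin
    edge's endpoints, in deterministic order."""
    from collections import deque

    dist = {origin_edge[0]: 0, origin_edge[1]: 0}
    dq = deque(origin_edge)
    while dq:
        u = dq.popleft()
        if dist[u] >= radius:
            continue
        for w in tree.adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                dq.append(w)
    out = []
    for u, v, _ in tree.edges():
        if min(dist.get(u, radius + 1), dist.get(v, radius + 1)) <= radius:
            out.append((u, v))
    return sorted(out)


# ---------------------------------------------------------------------------
# full protocol


def backbone_search(paln: PatternAlignment | Alignment, config: SearchConfig,
                    params: GTRParams | None = None,
                    alpha: float = 0.5,
                    starting_tree: Tree | None = None
                    ) -> tuple[Tree, SearchTrace]:
    """Backbone-constrained (or full, R = 1) maximum-likelihood search."""
    if isinstance(paln, Alignment):
        paln = compress_patterns(paln)
    trace = SearchTrace()
    if starting_tree is None:
        tree = parsimony_starting_tree(paln, config.seed,
                                       config.start_branch_length)
    else:
        tree = starting_tree.copy()

    if params is None:
        from .likelihood import empirical_frequencies

        params = GTRParams((1.0,) * 6, empirical_frequencies(paln))
    gamma = gamma_discretize(alpha, config.gamma_K)
    GammaEngine(tree, paln, params, gamma).optimize_branch_lengths(
        tol=config.branch_tol)
    if config.optimize_model_params:
        params, alpha = optimize_model(tree, paln, params, alpha,
                                       tol=config.branch_tol, K=config.gamma_K)
        gamma = gamma_discretize(alpha, config.gamma_K)
    cat_assignment = None
    if config.model == "cat":
        from .rates import CatEngine, derive_assignment

        single = CatEngine(tree, paln, params, np.ones(paln.n_patterns))
        single.optimize_branch_lengths(tol=config.branch_tol)
        cat_assignment = derive_assignment(tree, paln, params, config.cat_K)

    def full_engine(t: Tree, leaf_data=None):
        if config.model == "cat":
            from .rates import CatEngine

            return CatEngine(t, paln, params, cat_assignment.pattern_rates(),
                             leaf_data=leaf_data)
        return GammaEngine(t, paln, params, gamma, leaf_data=leaf_data)

    best = full_engine(tree).optimize_branch_lengths(tol=config.branch_tol)
    trace.params, trace.alpha = params, alpha

    for _ in range(config.max_cycles):
        if config.R < 1.0:
            clusters = assign_clusters(
                tree, BackboneConfig(config.R, config.m))
            labels = label_backbone(tree, clusters)
            search_tree, leaf_data = extract_backbone(tree, labels,
                                                      full_engine(tree))
            trace.backbone_tips.append(count_backbone_tips(labels))
            make_engine = lambda t: full_engine(t, leaf_data=leaf_data)
        else:
            search_tree = tree
            trace.backbone_tips.append(tree.n_tips)
            make_engine = full_engine
        cycle_lnl, moves = spr_cycle(search_tree, make_engine,
                                     radius=config.spr_radius)
        if config.R < 1.0:
            tree = _merge_backbone(tree, search_tree, labels)
        lnl = full_engine(tree).optimize_branch_lengths(tol=config.branch_tol)
        trace.cycle_lnl.append(lnl)
        trace.accepted_moves.append(moves)
        if lnl - best < config.tol:
            best = max(best, lnl)
            break
        best = lnl
    trace.final_lnl = best
    return tree, trace


def _merge_backbone(comprehensive: Tree, backbone: Tree, labels) -> Tree:
    """Graft the (possibly rearranged) backbone topology back onto the
    unchanged outside clades of the comprehensive tree."""
    merged = Tree()
    backbone_nodes = set(backbone.adj)
    adj: dict[int, dict[int, float]] = {}
    for u in comprehensive.adj:
        if u in backbone_nodes:
            row = dict(backbone.adj[u])
            for v, b in comprehensive.adj[u].items():
                if v not in backbone_nodes:
                    row[v] = b
            adj[u] = row
        else:
            adj[u] = dict(comprehensive.adj[u])
    merged.adj = adj
    merged.taxon_of = dict(comprehensive.taxon_of)
    merged.node_of_taxon = dict(comprehensive.node_of_taxon)
    merged._next_id = max(comprehensive._next_id, backbone._next_id)
    merged.validate()
    return merged


def evaluate_final(tree: Tree, paln: PatternAlignment | Alignment,
                   params: GTRParams, alpha: float, K: int = 4) -> float:
    """Rescore a final tree under GTR+Gamma so runs (including CAT-driven
    searches) are comparable on one scale."""
    if isinstance(paln, Alignment):
        paln = compress_patterns(paln)
    return GammaEngine(tree, paln, params, gamma_discretize(alpha, K)).loglik()
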