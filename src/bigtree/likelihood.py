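"""Felsenstein pruning under GTR+Gamma with joint 16-value numerical scaling.

Every pattern of an ancestral (conditional) probability vector holds
K x 4 values (K rate categories times 4 nucleotide states).  To avoid
underflow on deep trees, whenever *all* K x 4 entries of a pattern drop
below eps = 2^-256, all of them are multiplied by 2^256 and the pattern's
integer scaling count U is incremented.  Scaling counts of the two child
vectors add on combination, and at the virtual root the accumulated counts
are reversed on the log scale:

    log l(c) = (U_i(c) + U_j(c)) * log(eps) + log((1/K) * sum_k Q_k(c))

where Q_k(c) = sum_R pi_R L_R^(i)(c,k) sum_S P_RS(b_vr r_k) L_S^(j)(c,k).

Tip vectors are never scaled (their U is implicitly 0).  Because the model
is reversible and branch lengths multiply symmetric generators, the total
log likelihood is invariant under the placement of the virtual root.
"""

from __future__ import annotations

import logging
import numpy as np
from scipy.optimize import minimize_scalar

from .alignment import MASK_TO_VECTOR, PatternAlignment
from .model import GammaRates, GTRParams
from .tree import Tree

__all__ = [
    "EPS",
    "INV_EPS",
    "LOG_EPS",
    "LikelihoodUnderflowError",
    "GammaEngine",
    "compute_ancestral_vector",
    "apply_scaling",
    "apply_scaling_to_unit",
    "root_loglik",
    "tree_loglik",
    "optimize_branch_lengths",
    "optimize_model",
    "empirical_frequencies",
]

logger = logging.getLogger(__name__)

EPS = 2.0 ** -256
INV_EPS = 2.0 ** 256
LOG_EPS = float(np.log(EPS))

MIN_BRANCH = 1e-8
MAX_BRANCH = 10.0


class LikelihoodUnderflowError(ArithmeticError):
    """Per-pattern likelihood underflowed to zero despite joint scaling.

    This is the Gamma-model failure mode on very deep trees: the K x 4
    values of a pattern span more than the representable double range, so
    no joint scaling factor fits all of them.  Per-site rate categories
    (CAT) compress each pattern to 4 values and push the failure to much
    larger trees.
    """

    def __init__(self, pattern: int):
        super().__init__(
            f"site likelihood underflowed at pattern {pattern}; "
            "consider a per-site rate-category (CAT) model")
        self.pattern = pattern


# ---------------------------------------------------------------------------
# kernel primitives (shared verbatim by the standard and SEV kernels so that
# their results are bit-identical)


def half_vector(P: np.ndarray, L: np.ndarray) -> np.ndarray:
    """P(b r_k) summed over child states: out[p,k,a] = sum_b P[k,a,b] L[p,k,b]."""
    return np.einsum("kab,pkb->pka", P, L, optimize=False)


def compute_ancestral_vector(
    left: tuple[np.ndarray, np.ndarray],
    right: tuple[np.ndarray, np.ndarray],
    P_left: np.ndarray,
    P_right: np.ndarray,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Combine two child conditional vectors into the parent vector.

    left/right: (L, U) with L of shape (patterns, K, 4) and U of shape
    (patterns,).  P_left/P_right: (K, 4, 4) per-rate transition matrices.
    The parent's U starts as the sum of the children's counts; scaling is
    then applied per pattern.
    """
    Ll, Ul = left
    Lr, Ur = right
    if Ll.shape != Lr.shape:
        raise ValueError(f"child shape mismatch: {Ll.shape} vs {Lr.shape}")
    L = half_vector(P_left, Ll) * half_vector(P_right, Lr)
    U = Ul + Ur
    if scale:
        L, U = apply_scaling(L, U)
    return L, U


def apply_scaling(L: np.ndarray, U: np.ndarray,
                  epsilon: float = EPS) -> tuple[np.ndarray, np.ndarray]:
    """Scale patterns whose K x 4 entries are all below epsilon.

    Every entry of such a pattern is multiplied by 1/epsilon (2^256 at the
    default) and its scaling count is incremented by one.  Other patterns
    are untouched.  Returns (possibly copied) arrays.
    """
    flat_max = L.reshape(L.shape[0], -1).max(axis=1)
    mask = flat_max < epsilon
    if mask.any():
        L = L.copy()
        U = U.copy()
        L[mask] *= 1.0 / epsilon
        U[mask] += 1
    return L, U


def apply_scaling_to_unit(L: np.ndarray, U: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Alternative policy: rescale every pattern so its largest entry is 1.

    The accumulated factor is stored on the same log-epsilon scale as the
    threshold policy's integer counts (U becomes fractional), so the root
    reversal (U_i + U_j) * log(eps) applies unchanged.  Like the threshold
    policy, this does not survive patterns whose K x 4 values span more
    than the double range.
    """
    m = L.reshape(L.shape[0], -1).max(axis=1)
    pos = m > 0.0
    safe = np.where(pos, m, 1.0)
    L = L / safe[:, None, None]
    U = U + np.where(pos, np.log(safe) / LOG_EPS, 0.0)
    return L, U


def root_site_logl(
    Li: np.ndarray, Ui: np.ndarray,
    Lj: np.ndarray, Uj: np.ndarray,
    P_root: np.ndarray, pi: np.ndarray,
) -> np.ndarray:
    """Per-pattern log likelihood at the virtual root edge."""
    K = Li.shape[1]
    t = half_vector(P_root, Lj)
    q = np.einsum("pka,a->pk", Li * t, pi, optimize=False)
    l = q.sum(axis=1) / K
    if np.any(l <= 0.0) or not np.all(np.isfinite(l)):
        bad = int(np.flatnonzero((l <= 0.0) | ~np.isfinite(l))[0])
        raise LikelihoodUnderflowError(bad)
    return (Ui + Uj) * LOG_EPS + np.log(l)


def root_loglik(left, right, P_root, pi, weights) -> float:
    """Total log likelihood from the two root-edge conditional vectors."""
    Li, Ui = left
    Lj, Uj = right
    site = root_site_logl(Li, Ui, Lj, Uj, P_root, pi)
    return float(np.dot(np.asarray(weights, dtype=float), site))


# ---------------------------------------------------------------------------
# generic pruning engine


class PruningEngine:
    """Shared traversal/optimization machinery over an opaque vector type.

    Subclasses implement `_leaf`, `_combine` and `_root_site_logl`; the
    base class provides full-tree evaluation, per-edge conditional vectors
    on both sides of every branch, and branch-length optimization.

    `leaf_data` maps node ids to pre-computed conditional vectors (virtual
    tips); such nodes act as leaves regardless of taxon labels.
    """

    def __init__(self, tree: Tree, paln: PatternAlignment,
                 leaf_data: dict | None = None,
                 min_branch: float = MIN_BRANCH):
        self.tree = tree
        self.paln = paln
        self.leaf_data = leaf_data or {}
        self.min_branch = min_branch
        self._warned_clamp = False
        for node, taxon in tree.taxon_of.items():
            if node not in self.leaf_data and taxon not in paln.taxa:
                raise ValueError(f"taxon {taxon!r} missing from alignment")
        self.weights = np.asarray(paln.weights, dtype=float)

    # subclass API ----------------------------------------------------
    def _leaf(self, node: int):
        raise NotImplementedError

    def _combine(self, Vl, bl: float, Vr, br: float):
        raise NotImplementedError

    def _root_site_logl(self, Vi, Vj, b: float) -> np.ndarray:
        raise NotImplementedError

    # shared ----------------------------------------------------------
    def _clamp(self, b: float) -> float:
        if b < self.min_branch:
            if not self._warned_clamp:
                logger.info("branch lengths below %.2g clamped", self.min_branch)
                self._warned_clamp = True
            return self.min_branch
        return b

    def _is_leaf(self, node: int, parent: int) -> bool:
        if node in self.leaf_data:
            return True
        return all(v == parent for v in self.tree.adj[node])

    def conditional(self, root: int, exclude: int):
        """Conditional vector at `root` for the subtree away from `exclude`."""
        vecs: dict[int, object] = {}
        for u, parent in self.tree.postorder_from(root, exclude=exclude):
            p = parent if parent is not None else exclude
            if self._is_leaf(u, p):
                vecs[u] = self._leaf(u)
            else:
                kids = [v for v in sorted(self.tree.adj[u]) if v != p]
                if len(kids) != 2:
                    raise ValueError(f"node {u} has {len(kids)} children")
                vecs[u] = self._combine(
                    vecs[kids[0]], self._clamp(self.tree.adj[u][kids[0]]),
                    vecs[kids[1]], self._clamp(self.tree.adj[u][kids[1]]))
                del vecs[kids[0]], vecs[kids[1]]
        return vecs[root]

    def default_root_edge(self) -> tuple[int, int]:
        if self.tree.node_of_taxon:
            tip = self.tree.node_of_taxon[min(self.tree.node_of_taxon)]
        else:  # reduced tree made entirely of virtual tips
            tip = min(self.leaf_data)
        return tip, next(iter(self.tree.adj[tip]))

    def site_logl(self, root_edge: tuple[int, int] | None = None) -> np.ndarray:
        if root_edge is None:
            root_edge = self.default_root_edge()
        i, j = root_edge
        Vi = self.conditional(i, j)
        Vj = self.conditional(j, i)
        return self._root_site_logl(Vi, Vj, self._clamp(self.tree.adj[i][j]))

    def loglik(self, root_edge: tuple[int, int] | None = None) -> float:
        return float(np.dot(self.weights, self.site_logl(root_edge)))

    # per-edge vectors on both sides of every branch --------------------
    def edge_vectors(self) -> dict[tuple[int, int], tuple]:
        """For every edge (u, v): (V_away_from_v_at_u, V_subtree_at_v).

        Computed with one downward and one upward pass, O(nodes) combines
        total.  Keys are both orientations.
        """
        tree = self.tree
        root = None
        for u in tree.nodes():
            if not tree.is_tip(u) and u not in self.leaf_data:
                root = u
                break
        if root is None:
            raise ValueError("tree has no internal node")
        order = tree.postorder_from(root)
        down: dict[int, object] = {}
        for u, parent in order:
            if u == root:
                continue
            if self._is_leaf(u, parent):
                down[u] = self._leaf(u)
            else:
                kids = [v for v in sorted(tree.adj[u]) if v != parent]
                down[u] = self._combine(
                    down[kids[0]], self._clamp(tree.adj[u][kids[0]]),
                    down[kids[1]], self._clamp(tree.adj[u][kids[1]]))
        up: dict[int, object] = {}
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            u, parent = stack.pop()
            kids = [v for v in sorted(tree.adj[u]) if v != parent]
            for v in kids:
                others = [w for w in kids if w != v]
                pieces = [(down[w], self._clamp(tree.adj[u][w])) for w in others]
                if parent is not None:
                    pieces.append((up[u], self._clamp(tree.adj[u][parent])))
                if len(pieces) == 1:
                    # degree-2 situation cannot occur on valid binary trees
                    raise ValueError("unexpected tree shape")
                up[v] = self._combine(pieces[0][0], pieces[0][1],
                                      pieces[1][0], pieces[1][1])
                if not self._is_leaf(v, u):
                    stack.append((v, u))
        parent_of = {u: p for u, p in order}
        out: dict[tuple[int, int], tuple] = {}
        for u, v, _ in tree.edges():
            child = v if parent_of.get(v) == u else u
            par = v if child == u else u
            out[(par, child)] = (up[child], down[child])
            out[(child, par)] = (down[child], up[child])
        return out

    def edge_loglik(self, pair: tuple, b: float) -> float:
        A, B = pair
        site = self._root_site_logl(A, B, self._clamp(b))
        return float(np.dot(self.weights, site))

    def optimize_branch_lengths(self, tol: float = 0.1, max_sweeps: int = 64,
                                xatol: float = 1e-6) -> float:
        """Sweep all branches with bounded scalar (Brent-style) optimization
        until the total log likelihood improves by less than `tol`.

        Each sweep computes per-edge conditional vectors once and optimizes
        every branch against them; the total is re-evaluated at the end of
        the sweep and a sweep that fails to improve is rolled back, so the
        reported likelihood never decreases.
        """
        best = self.loglik()
        for _ in range(max_sweeps):
            saved = {(u, v): b for u, v, b in self.tree.edges()}
            vectors = self.edge_vectors()
            for (u, v), b0 in saved.items():
                pair = vectors[(u, v)]
                res = minimize_scalar(
                    lambda b: -self.edge_loglik(pair, b),
                    bounds=(self.min_branch, MAX_BRANCH),
                    method="bounded", options={"xatol": xatol})
                self.tree.set_branch_length(u, v, float(res.x))
            cur = self.loglik()
            if cur < best:
                for (u, v), b in saved.items():
                    self.tree.set_branch_length(u, v, b)
                break
            improved = cur - best
            best = cur
            if improved < tol:
                break
        else:
            logger.warning("branch-length optimization hit max_sweeps=%d",
                           max_sweeps)
        return best


# ---------------------------------------------------------------------------
# GTR+Gamma engine (standard dense kernel)


class GammaEngine(PruningEngine):
    """Dense GTR+Gamma pruning engine.

    Conditional vectors are (L, U) pairs with L of shape
    (patterns, K, 4) and per-pattern scaling counts U.
    """

    def __init__(self, tree: Tree, paln: PatternAlignment, params: GTRParams,
                 gamma: GammaRates, leaf_data: dict | None = None,
                 min_branch: float = MIN_BRANCH,
                 scaling_policy: str = "threshold"):
        super().__init__(tree, paln, leaf_data, min_branch)
        self.params = params
        self.gamma = gamma
        self.rates = gamma.as_array()
        self.pi = params.pi
        self.K = gamma.K
        if scaling_policy not in ("threshold", "largest-to-one"):
            raise ValueError(f"unknown scaling policy {scaling_policy!r}")
        self.scaling_policy = scaling_policy

    def _pmats(self, b: float) -> np.ndarray:
        return self.params.transition_matrices(b, self.rates)

    def _leaf(self, node: int):
        if node in self.leaf_data:
            return self.leaf_data[node]
        taxon = self.tree.taxon_of[node]
        tipv = self.paln.tip_vectors(taxon)  # (P, 4)
        P = tipv.shape[0]
        L = np.broadcast_to(tipv[:, None, :], (P, self.K, 4))
        U = np.zeros(P, dtype=np.int64)
        return L, U

    def _combine(self, Vl, bl, Vr, br):
        if self.scaling_policy == "largest-to-one":
            L, U = compute_ancestral_vector(
                Vl, Vr, self._pmats(bl), self._pmats(br), scale=False)
            return apply_scaling_to_unit(L, U)
        return compute_ancestral_vector(Vl, Vr, self._pmats(bl), self._pmats(br))

    def _root_site_logl(self, Vi, Vj, b: float) -> np.ndarray:
        Li, Ui = Vi
        Lj, Uj = Vj
        return root_site_logl(Li, Ui, Lj, Uj, self._pmats(b), self.pi)


# ---------------------------------------------------------------------------
# convenience wrappers


def tree_loglik(tree: Tree, paln: PatternAlignment, params: GTRParams,
                gamma: GammaRates, kernel: str = "standard",
                root_edge: tuple[int, int] | None = None) -> float:
    """Log likelihood of an alignment on a tree under GTR+Gamma."""
    engine = make_engine(tree, paln, params, gamma, kernel)
    return engine.loglik(root_edge)


def make_engine(tree: Tree, paln: PatternAlignment, params: GTRParams,
                gamma: GammaRates, kernel: str = "standard",
                leaf_data: dict | None = None) -> PruningEngine:
    if kernel == "standard":
        return GammaEngine(tree, paln, params, gamma, leaf_data)
    if kernel in ("sev", "sev-memsave"):
        from .sev import SevEngine

        return SevEngine(tree, paln, params, gamma, leaf_data,
                         memory_saving=(kernel == "sev-memsave"))
    raise ValueError(f"unknown kernel {kernel!r}")


def optimize_branch_lengths(tree: Tree, paln: PatternAlignment,
                            params: GTRParams, gamma: GammaRates,
                            tol: float = 0.1, max_sweeps: int = 64) -> float:
    """Optimize all branch lengths in place; returns the final LnL."""
    engine = GammaEngine(tree, paln, params, gamma)
    return engine.optimize_branch_lengths(tol=tol, max_sweeps=max_sweeps)


def empirical_frequencies(paln: PatternAlignment) -> tuple[float, ...]:
    """Base frequencies from observed states, ambiguity spread uniformly
    over its compatible states; gaps ignored."""
    counts = np.zeros(4)
    for t, taxon in enumerate(paln.taxa):
        masks = paln.patterns[t]
        vec = MASK_TO_VECTOR[masks]  # (P, 4)
        informative = masks != 15
        if informative.any():
            v = vec[informative] / vec[informative].sum(axis=1, keepdims=True)
            counts += (v * paln.weights[informative, None]).sum(axis=0)
    if counts.sum() == 0:
        return (0.25, 0.25, 0.25, 0.25)
    freqs = counts / counts.sum()
    freqs = np.clip(freqs, 1e-6, None)
    freqs = freqs / freqs.sum()
    return tuple(float(f) for f in freqs)


def optimize_model(tree: Tree, paln: PatternAlignment,
                   start_params: GTRParams, start_alpha: float,
                   tol: float = 0.1, K: int = 4,
                   frequency_mode: str = "empirical",
                   max_rounds: int = 8) -> tuple[GTRParams, float]:
    """Coordinate-wise (Brent) optimization of GTR exchangeabilities and
    the Gamma shape alpha at fixed tree and branch lengths.

    frequency_mode: 'empirical' (default) uses observed base frequencies;
    'fixed' keeps the frequencies of `start_params`; 'ml' optimizes three
    frequency logits coordinate-wise like the other parameters.
    """
    from .model import gamma_discretize

    if frequency_mode == "empirical":
        freqs = empirical_frequencies(paln)
    else:
        freqs = start_params.frequencies
    ex = list(start_params.exchangeabilities[:5]) + [1.0]
    logits = list(np.log(np.asarray(freqs) / freqs[3]))[:3]
    alpha = float(start_alpha)

    def build(exch, lg, a):
        if frequency_mode == "ml":
            z = np.exp(np.array(list(lg) + [0.0]))
            fr = tuple(z / z.sum())
        else:
            fr = freqs
        return GTRParams(tuple(exch), fr), a

    def score(exch, lg, a) -> float:
        params, a = build(exch, lg, a)
        engine = GammaEngine(tree, paln, params, gamma_discretize(a, K))
        try:
            return engine.loglik()
        except LikelihoodUnderflowError:
            return -np.inf

    best = score(ex, logits, alpha)
    for _ in range(max_rounds):
        start_best = best
        for i in range(5):  # free exchangeabilities (GT fixed at 1)
            def f(logr, i=i):
                trial = list(ex)
                trial[i] = float(np.exp(logr))
                return -score(trial, logits, alpha)
            res = minimize_scalar(f, bounds=(np.log(1e-3), np.log(1e3)),
                                  method="bounded", options={"xatol": 1e-3})
            if -res.fun > best:
                ex[i] = float(np.exp(res.x))
                best = -res.fun
        if frequency_mode == "ml":
            for i in range(3):
                def f(lg, i=i):
                    trial = list(logits)
                    trial[i] = float(lg)
                    return -score(ex, trial, alpha)
                res = minimize_scalar(f, bounds=(-8.0, 8.0), method="bounded",
                                      options={"xatol": 1e-3})
                if -res.fun > best:
                    logits[i] = float(res.x)
                    best = -res.fun

        def fa(loga):
            return -score(ex, logits, float(np.exp(loga)))
        res = minimize_scalar(fa, bounds=(np.log(0.02), np.log(100.0)),
                              method="bounded", options={"xatol": 1e-3})
        if -res.fun > best:
            alpha = float(np.exp(res.x))
            best = -res.fun
        if best - start_best < tol:
            break
    params, alpha = build(ex, logits, alpha)
    return params, alpha
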