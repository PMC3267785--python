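"""Gap-tracking Subtree Equality Vectors (SEVs).

Structured missing data dominates multi-gene alignments: a taxon that
lacks a gene contributes an all-gap block.  For any subtree whose tips are
all gap/undetermined at a pattern, the conditional vector at the subtree
root is the same for every such pattern (it depends only on the subtree's
topology and branch lengths, not on the pattern), so the work and the
storage for those patterns can be skipped: one shared "signal" column
stands in for all of them.

Each node carries a bit vector with one bit per pattern (1 = all tips in
the subtree are gap at that pattern); a parent's bits are the bitwise AND
of its children's bits, computed alongside the pruning recursion.  The SEV
kernel evaluates the recursion only where the parent bit is 0 and uses the
identical floating-point operations as the dense kernel, so total log
likelihoods agree bit for bit.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .alignment import PatternAlignment
from .likelihood import (
    GammaEngine,
    LikelihoodUnderflowError,
    PruningEngine,
    compute_ancestral_vector,
    root_site_logl,
)
from .model import GammaRates, GTRParams
from .tree import Tree

__all__ = [
    "SevVector",
    "SevEngine",
    "SevStorage",
    "tip_gap_vector",
    "propagate_gap_vector",
    "gap_vectors_for_rooting",
    "sev_memory_footprint",
    "standard_memory_footprint",
    "resize_on_topology_change",
    "auto_select_kernel",
]


def tip_gap_vector(masks_or_bits) -> np.ndarray:
    """Gap bit vector for a tip: True where the character is '-'/'?'/'N'
    (i.e. the full state mask).  Accepts a state-mask array or a sequence
    string."""
    arr = masks_or_bits
    if isinstance(arr, str):
        from .alignment import CHAR_TO_MASK

        arr = np.array([CHAR_TO_MASK[c] for c in arr.upper().replace("?", "-")],
                       dtype=np.uint8)
    return np.asarray(arr) == 15


def propagate_gap_vector(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Parent bits = left AND right (a subtree is all-gap at a pattern iff
    both child subtrees are)."""
    left = np.asarray(left, dtype=bool)
    right = np.asarray(right, dtype=bool)
    if left.shape != right.shape:
        raise ValueError(f"gap vector length mismatch: {left.shape} vs {right.shape}")
    return left & right


@dataclass
class SevVector:
    """Conditional vector with all-gap patterns elided.

    gap: (P,) bool, the subtree's all-gap bits.
    pos: (P,) int64 mapping pattern -> row of the dense arrays (-1 for gap).
    L: (P - popcount, K, 4) conditional likelihoods of stored patterns.
    U: (P - popcount,) scaling counts of stored patterns.
    sig_L: (1, K, 4) shared all-gap signal column; sig_U: (1,) its count.
    """

    gap: np.ndarray
    pos: np.ndarray
    L: np.ndarray
    U: np.ndarray
    sig_L: np.ndarray
    sig_U: np.ndarray

    @property
    def popcount(self) -> int:
        return int(self.gap.sum())

    def lookup(self, pattern: int) -> tuple[np.ndarray, int]:
        """Per-pattern (K, 4) likelihoods; all-gap patterns return the
        shared signal column."""
        if self.gap[pattern]:
            return self.sig_L[0], int(self.sig_U[0])
        return self.L[self.pos[pattern]], int(self.U[self.pos[pattern]])

    def full(self) -> tuple[np.ndarray, np.ndarray]:
        """Expand to dense (P, K, 4) and (P,) arrays."""
        P = self.gap.shape[0]
        K = self.L.shape[1] if self.L.size else self.sig_L.shape[1]
        L = np.empty((P, K, 4))
        U = np.empty(P, dtype=np.int64)
        L[self.gap] = self.sig_L
        U[self.gap] = self.sig_U[0]
        if self.L.shape[0]:
            L[~self.gap] = self.L
            U[~self.gap] = self.U
        return L, U


def _make_pos(gap: np.ndarray) -> np.ndarray:
    pos = np.full(gap.shape[0], -1, dtype=np.int64)
    pos[~gap] = np.arange(int((~gap).sum()))
    return pos


def _rows_for(v: SevVector, parent_gap: np.ndarray, idx: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Child rows aligned to the parent's active patterns.

    When the child's gap vector equals the parent's, its dense storage is
    already in the right order and is used as-is (the common case inside a
    gene-presence block); otherwise rows are gathered, substituting the
    signal column where the child subtree is all-gap."""
    if v.gap.shape == parent_gap.shape and np.array_equal(v.gap, parent_gap):
        return v.L, v.U
    return _gather(v, idx)


def _gather(v: SevVector, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows of v for the given pattern indices, substituting the signal
    column where v is all-gap."""
    gapped = v.gap[idx]
    if v.L.shape[0] == 0:
        K = v.sig_L.shape[1]
        return (np.broadcast_to(v.sig_L, (len(idx), K, 4)),
                np.full(len(idx), v.sig_U[0], dtype=np.int64))
    safe = np.where(gapped, 0, v.pos[idx])
    L = v.L[safe]
    U = v.U[safe]
    if gapped.any():
        L = np.where(gapped[:, None, None], v.sig_L, L)
        U = np.where(gapped, v.sig_U[0], U)
    return L, U


class SevEngine(PruningEngine):
    """GTR+Gamma pruning engine that skips all-gap subtree patterns.

    Produces log likelihoods bit-identical to `GammaEngine` (the same
    kernel primitives run on the same values in the same order); only the
    set of patterns actually computed per node differs.  With
    `memory_saving` the reduced storage is the persistent representation
    and reallocation is tracked per node through an allocation counter.
    """

    def __init__(self, tree: Tree, paln: PatternAlignment, params: GTRParams,
                 gamma: GammaRates, leaf_data: dict | None = None,
                 memory_saving: bool = False, min_branch: float = 1e-8):
        super().__init__(tree, paln, leaf_data, min_branch)
        self.params = params
        self.gamma = gamma
        self.rates = gamma.as_array()
        self.pi = params.pi
        self.K = gamma.K
        self.memory_saving = memory_saving
        self.allocation_count = 0
        self._alloc_popcounts: dict[int, int] = {}

    def _pmats(self, b: float) -> np.ndarray:
        return self.params.transition_matrices(b, self.rates)

    def _leaf(self, node: int) -> SevVector:
        if node in self.leaf_data:
            data = self.leaf_data[node]
            if isinstance(data, SevVector):
                return data
            L, U = data
            gap = np.zeros(L.shape[0], dtype=bool)
            return SevVector(gap, _make_pos(gap), L, np.asarray(U),
                             np.ones((1, self.K, 4)),
                             np.zeros(1, dtype=np.int64))
        taxon = self.tree.taxon_of[node]
        gap = self.paln.tip_gap_bits(taxon)
        tipv = self.paln.tip_vectors(taxon)[~gap]
        A = tipv.shape[0]
        L = np.broadcast_to(tipv[:, None, :], (A, self.K, 4))
        return SevVector(gap, _make_pos(gap), L, np.zeros(A, dtype=np.int64),
                         np.ones((1, self.K, 4)), np.zeros(1, dtype=np.int64))

    def _combine(self, Vl: SevVector, bl: float, Vr: SevVector, br: float
                 ) -> SevVector:
        Pl, Pr = self._pmats(bl), self._pmats(br)
        gap = propagate_gap_vector(Vl.gap, Vr.gap)
        idx = np.flatnonzero(~gap)
        Ll, Ul = _rows_for(Vl, gap, idx)
        Lr, Ur = _rows_for(Vr, gap, idx)
        L, U = compute_ancestral_vector((Ll, Ul), (Lr, Ur), Pl, Pr)
        if gap.any():
            sig_L, sig_U = compute_ancestral_vector(
                (Vl.sig_L, Vl.sig_U), (Vr.sig_L, Vr.sig_U), Pl, Pr)
        else:
            # gap-free node: neither this signal column nor any ancestor's
            # can ever be read (ancestor gap vectors are subsets)
            sig_L = np.ones((1, L.shape[1], 4))
            sig_U = np.zeros(1, dtype=np.int64)
        return SevVector(gap, _make_pos(gap), L, U, sig_L, sig_U)

    def _root_site_logl(self, Vi: SevVector, Vj: SevVector, b: float
                        ) -> np.ndarray:
        P_root = self._pmats(b)
        both_gap = Vi.gap & Vj.gap
        idx = np.flatnonzero(~both_gap)
        out = np.empty(both_gap.shape[0])
        if idx.size:
            Li, Ui = _rows_for(Vi, both_gap, idx)
            Lj, Uj = _rows_for(Vj, both_gap, idx)
            try:
                out[idx] = root_site_logl(Li, Ui, Lj, Uj, P_root, self.pi)
            except LikelihoodUnderflowError as exc:
                raise LikelihoodUnderflowError(int(idx[exc.pattern])) from None
        if both_gap.any():
            sig = root_site_logl(Vi.sig_L, Vi.sig_U, Vj.sig_L, Vj.sig_U,
                                 P_root, self.pi)
            out[both_gap] = sig[0]
        return out

    # memory-saving bookkeeping ---------------------------------------
    def register_allocation(self, node: int, popcount: int) -> bool:
        """Record the vector length required at `node`; reallocate (and
        count it) only when the popcount changed.  Returns True when a
        reallocation happened."""
        old = self._alloc_popcounts.get(node)
        if old == popcount:
            return False
        self._alloc_popcounts[node] = popcount
        self.allocation_count += 1
        return True


# ---------------------------------------------------------------------------
# gap vectors and memory accounting


def gap_vectors_for_rooting(tree: Tree, paln: PatternAlignment,
                            root_edge: tuple[int, int] | None = None
                            ) -> dict[int, np.ndarray]:
    """All-gap bit vectors of every node for a given virtual rooting.

    Tips get their sequence gap bits; each inner node gets the AND of its
    two children under the rooting at `root_edge`.
    """
    if root_edge is None:
        tip = tree.node_of_taxon[min(tree.node_of_taxon)]
        root_edge = (tip, next(iter(tree.adj[tip])))
    i, j = root_edge
    bits: dict[int, np.ndarray] = {}

    def fill(root: int, exclude: int) -> None:
        for u, parent in tree.postorder_from(root, exclude=exclude):
            p = parent if parent is not None else exclude
            if tree.is_tip(u):
                bits[u] = paln.tip_gap_bits(tree.taxon_of[u])
            else:
                kids = [v for v in sorted(tree.adj[u]) if v != p]
                bits[u] = propagate_gap_vector(bits[kids[0]], bits[kids[1]])

    fill(i, j)
    fill(j, i)
    return bits


def standard_memory_footprint(tree: Tree, pattern_count: int, K: int = 4,
                              bytes_per_entry: int = 8) -> int:
    """Bytes for dense ancestral vectors (plus scaling counts) at every
    inner node."""
    n_inner = len(tree.inner_nodes())
    per_node = pattern_count * 4 * K * bytes_per_entry + pattern_count * 8
    return n_inner * per_node


def sev_memory_footprint(tree: Tree, gap_vectors: dict[int, np.ndarray],
                         K: int = 4, bytes_per_entry: int = 8) -> int:
    """Bytes for SEV ancestral vectors: per inner node, only the patterns
    whose gap bit is 0 are stored, plus one shared signal column and the
    scaling counts of the stored patterns."""
    total = 0
    for node in tree.inner_nodes():
        bits = gap_vectors[node]
        stored = int(bits.shape[0] - bits.sum()) + 1
        total += stored * 4 * K * bytes_per_entry + stored * 8
    return total


@dataclass
class SevStorage:
    """Allocation-counting stand-in for the dynamic free()/malloc()
    management of per-node vector storage."""

    popcount: int
    allocations: int = 1

    def resize(self, new_popcount: int) -> bool:
        if new_popcount == self.popcount:
            return False
        self.popcount = new_popcount
        self.allocations += 1
        return True


def resize_on_topology_change(storage: SevStorage,
                              new_gap_vector: np.ndarray) -> bool:
    """Reallocate a node's vector storage only if the all-gap popcount
    changed (contents must be recomputed either way)."""
    return storage.resize(int(np.asarray(new_gap_vector).sum()))


# ---------------------------------------------------------------------------
# kernel auto-selection


def auto_select_kernel(tree: Tree, paln: PatternAlignment, params: GTRParams,
                       gamma: GammaRates, threshold: float = 0.8,
                       repeats: int = 3) -> tuple[str, dict[str, float]]:
    """Time one full tree traversal per kernel and pick the SEV kernel iff
    it is at least (1 - threshold) faster than the standard kernel.

    Default threshold 0.8 selects SEV when its traversal time is below 80%
    of the standard time (i.e. at least 20% faster).  Best-of-`repeats`
    monotonic-clock timings are used to damp noise.
    """
    std = GammaEngine(tree, paln, params, gamma)
    sev = SevEngine(tree, paln, params, gamma)

    def best_time(engine) -> float:
        best = float("inf")
        for _ in range(repeats):
            t0 = time.perf_counter()
            engine.site_logl()
            best = min(best, time.perf_counter() - t0)
        return best

    t_std = best_time(std)
    t_sev = best_time(sev)
    choice = "sev" if t_sev < threshold * t_std else "standard"
    return choice, {"standard": t_std, "sev": t_sev, "threshold": threshold}
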