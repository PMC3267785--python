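"""Backbone construction: clustering tips into virtual tips.

To search on a reduced tree, the n tips of a comprehensive tree are
grouped into c = ceil(n * R) clusters (R the reduction factor) by
average-linkage hierarchical clustering of patristic distances.  The
O(n^2) distance matrix is avoided by decomposing the tree at its
innermost node into subtrees of at most m tips (default 1024) and
clustering each partial matrix separately, with per-matrix cluster
budgets c_i allocated proportionally to subtree size.

Nodes are then labeled inside / boundary / outside: the backbone is the
inside+boundary node set, boundary nodes become its leaves ("virtual
tips" when they are ancestral nodes), and the conditional probability
vector of a virtual tip summarizes its excluded clade so that the
likelihood of the *comprehensive* tree is still computed exactly through
the reduced tree.  A non-monophyletic cluster necessarily induces more
than one boundary tip, so the realized backbone tip count is >= c.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .tree import Tree

__all__ = [
    "BackboneConfig",
    "ClusterAssignment",
    "BackboneLabels",
    "ideal_backbone_size",
    "cluster_count",
    "find_innermost_node",
    "decompose_subtrees",
    "allocate_clusters",
    "average_linkage",
    "cut_dendrogram",
    "assign_clusters",
    "label_backbone",
    "extract_backbone",
    "count_backbone_tips",
    "induced_subtree",
]

logger = logging.getLogger(__name__)

INSIDE = "inside"
BOUNDARY = "boundary"
OUTSIDE = "outside"

CRITERIA = ("max_remainder", "min_var_stl", "min_var_tipdist", "max_min_tipdist")


@dataclass(frozen=True)
class BackboneConfig:
    """Reduction factor R in (0, 1], partial-matrix tip cap m, and the
    innermost-node criterion."""

    R: float
    m: int = 1024
    innermost_criterion: str = "max_remainder"

    def __post_init__(self) -> None:
        if not 0.0 < self.R <= 1.0:
            raise ValueError(f"R must be in (0, 1], got {self.R}")
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.innermost_criterion not in CRITERIA:
            raise ValueError(f"unknown criterion {self.innermost_criterion!r}")
        if self.R <= 0.25:
            logger.warning("R = %.3f <= 0.25; aggressive reductions can "
                           "discard phylogenetic signal", self.R)


def ideal_backbone_size(n: int, R: float) -> float:
    """n * R before ceiling: the ideal number of backbone tips."""
    return n * R


def cluster_count(n: int, R: float) -> int:
    """c = ceil(n * R), the number of clusters requested."""
    return int(math.ceil(n * R))


@dataclass
class ClusterAssignment:
    tip_to_cluster: dict[str, int]
    c: int
    budgets: list[int]
    subtree_roots: list[tuple[int, int]]  # directed edges (parent, root)
    subtree_tip_counts: list[int]

    def cluster_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for cid in self.tip_to_cluster.values():
            sizes[cid] = sizes.get(cid, 0) + 1
        return sizes


@dataclass
class BackboneLabels:
    label: dict[int, str]
    cluster_of: dict[int, int] = field(default_factory=dict)

    def boundary_nodes(self) -> list[int]:
        return sorted(u for u, l in self.label.items() if l == BOUNDARY)

    def backbone_nodes(self) -> set[int]:
        return {u for u, l in self.label.items() if l in (INSIDE, BOUNDARY)}


# ---------------------------------------------------------------------------
# innermost node


def find_innermost_node(tree: Tree, criterion: str = "max_remainder") -> int:
    """Select the innermost node of the tree.

    Default: the inner node j maximizing stl(T) - max of the three
    outgoing directed subtree lengths (stl includes the attaching branch,
    so the three stl values at any node sum to the total tree length).
    Ties break toward the lowest node id.
    """
    inner = tree.inner_nodes()
    if not inner:
        raise ValueError("tree has no inner node")
    stl = tree.all_directed_subtree_lengths()
    total = tree.total_length()

    if criterion in ("max_remainder", "min_var_stl"):
        best_node, best_key = None, None
        for u in inner:
            vals = [stl[(u, v)] for v in sorted(tree.adj[u])]
            if criterion == "max_remainder":
                key = total - max(vals)  # maximize
                key = -key  # minimize below
            else:
                key = float(np.var(vals))
            if best_key is None or key < best_key - 1e-15:
                best_node, best_key = u, key
        return best_node
    # node-to-tip distance criteria
    tips = tree.tips()
    best_node, best_key = None, None
    for u in inner:
        dist = tree.distances_from(u)
        d = np.array([dist[t] for t in tips])
        if criterion == "min_var_tipdist":
            key = float(np.var(d))
        else:  # max_min_tipdist
            key = -float(d.min())
        if best_key is None or key < best_key - 1e-15:
            best_node, best_key = u, key
    return best_node


# ---------------------------------------------------------------------------
# subtree decomposition


def _directed_tip_counts(tree: Tree) -> dict[tuple[int, int], int]:
    root = next(iter(tree.adj))
    order = tree.postorder_from(root)
    count: dict[tuple[int, int], int] = {}
    for u, parent in order:
        if parent is None:
            continue
        if tree.is_tip(u):
            count[(parent, u)] = 1
        else:
            count[(parent, u)] = sum(count[(u, v)] for v in tree.adj[u]
                                     if v != parent)
    stack: list[tuple[int, int | None]] = [(root, None)]
    n = tree.n_tips
    while stack:
        u, parent = stack.pop()
        for v in tree.adj[u]:
            if v == parent:
                continue
            count[(v, u)] = n - count[(u, v)]
            stack.append((v, u))
    return count


def decompose_subtrees(tree: Tree, start_node: int, m: int
                       ) -> list[tuple[int, int]]:
    """Depth-first decomposition from the innermost node.

    Returns directed edges (parent, root): the subtree on the root side of
    each edge has <= m tips and is maximal on its root-to-tip path; the
    subtree tip sets partition the tips of the tree.
    """
    counts = _directed_tip_counts(tree)
    roots: list[tuple[int, int]] = []

    def descend(parent: int, node: int) -> None:
        if counts[(parent, node)] <= m:
            roots.append((parent, node))
            return
        for child in sorted(tree.adj[node]):
            if child != parent:
                descend(node, child)

    for child in sorted(tree.adj[start_node]):
        descend(start_node, child)
    return roots


# ---------------------------------------------------------------------------
# cluster budgets


def allocate_clusters(subtree_sizes, c: int) -> list[int]:
    """Distribute c clusters across partial matrices proportionally.

    First pass rounds c * n_i / n half-up; the overhead or deficit is then
    distributed proportionally and finally settled one cluster at a time
    in decreasing-n_i order, keeping 1 <= c_i <= n_i throughout.
    """
    sizes = [int(x) for x in subtree_sizes]
    if any(s < 1 for s in sizes):
        raise ValueError("subtree sizes must be >= 1")
    n = sum(sizes)
    k = len(sizes)
    if not 1 <= c <= n:
        raise ValueError(f"need 1 <= c <= {n}, got c={c}")
    if c < k:
        raise ValueError(f"cannot give each of {k} partial matrices a cluster "
                         f"with only c={c}")
    cbar = [math.floor(0.5 + c * s / n) for s in sizes]
    ci = [min(max(x, 1), s) for x, s in zip(cbar, sizes)]
    delta = c - sum(ci)
    if delta != 0:
        # proportional pass
        ci = [min(max(math.floor(0.5 + x + delta * x / c), 1), s)
              for x, s in zip(ci, sizes)]
        delta = c - sum(ci)
    order = sorted(range(k), key=lambda i: (-sizes[i], i))
    guard = 0
    while delta != 0:
        moved = False
        for i in order:
            if delta > 0 and ci[i] < sizes[i]:
                ci[i] += 1
                delta -= 1
                moved = True
            elif delta < 0 and ci[i] > 1:
                ci[i] -= 1
                delta += 1
                moved = True
            if delta == 0:
                break
        if not moved:
            raise RuntimeError("cluster allocation cannot settle")
        guard += 1
        if guard > n:
            raise RuntimeError("cluster allocation failed to terminate")
    return ci


# ---------------------------------------------------------------------------
# hierarchical clustering


def average_linkage(labels, matrix) -> np.ndarray:
    """UPGMA-style unweighted average-linkage merge dendrogram.

    Returns a scipy linkage matrix over the given labels (rows of
    `matrix`).  A single leaf yields an empty dendrogram.
    """
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != len(labels):
        raise ValueError("matrix does not match labels")
    if len(labels) == 1:
        return np.empty((0, 4))
    return linkage(squareform(m, checks=False), method="average")


def cut_dendrogram(Z: np.ndarray, n_leaves: int, k: int) -> np.ndarray:
    """Undo the last k - 1 merges: exactly k clusters, labeled 0..k-1 in
    order of their smallest member index."""
    if not 1 <= k <= n_leaves:
        raise ValueError(f"need 1 <= k <= {n_leaves}, got {k}")
    parent = list(range(n_leaves))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges = n_leaves - k
    members: dict[int, int] = {}  # scipy cluster index -> representative
    for row in range(merges):
        i, j = int(Z[row, 0]), int(Z[row, 1])
        ri = find(members.get(i, i)) if i >= n_leaves else find(i)
        rj = find(members.get(j, j)) if j >= n_leaves else find(j)
        parent[max(ri, rj)] = min(ri, rj)
        members[n_leaves + row] = min(ri, rj)
    reps = [find(i) for i in range(n_leaves)]
    order = sorted(set(reps))
    remap = {r: idx for idx, r in enumerate(order)}
    return np.array([remap[r] for r in reps], dtype=np.int64)


# ---------------------------------------------------------------------------
# orchestration


def assign_clusters(tree: Tree, config: BackboneConfig) -> ClusterAssignment:
    """Assign every tip to one of c = ceil(n * R) clusters.

    Innermost-node selection, subtree decomposition under the tip cap m,
    one partial patristic matrix per subtree (memory O(m^2)), per-matrix
    average-linkage clustering cut at the allocated budget.  Cluster ids
    are globally unique.
    """
    n = tree.n_tips
    c = cluster_count(n, config.R)
    innermost = find_innermost_node(tree, config.innermost_criterion)
    roots = decompose_subtrees(tree, innermost, config.m)
    subtree_taxa = [
        sorted(tree.taxon_of[t] for t in tree.subtree_tips(v, p))
        for p, v in roots
    ]
    sizes = [len(tx) for tx in subtree_taxa]
    budgets = allocate_clusters(sizes, c)
    tip_to_cluster: dict[str, int] = {}
    next_id = 0
    for taxa, budget in zip(subtree_taxa, budgets):
        if len(taxa) == 1:
            tip_to_cluster[taxa[0]] = next_id
            next_id += 1
            continue
        _, dm = tree.patristic_matrix(taxa)
        Z = average_linkage(taxa, dm)
        labels = cut_dendrogram(Z, len(taxa), budget)
        for taxon, lab in zip(taxa, labels):
            tip_to_cluster[taxon] = next_id + int(lab)
        next_id += budget
    return ClusterAssignment(tip_to_cluster, c, budgets, roots, sizes)


def label_backbone(tree: Tree, clusters: ClusterAssignment,
                   decomposition: list[tuple[int, int]] | None = None
                   ) -> BackboneLabels:
    """Label nodes inside / boundary / outside.

    Inner nodes start inside; tips in singleton clusters are boundary,
    other tips outside.  A post-order pass from each subtree root groups
    monophyletic same-cluster regions into outside blocks and promotes the
    node above a cluster conflict back to inside (its children become
    boundary).  A subtree root left outside — its whole subtree is one
    cluster — is itself relabeled boundary, so no edge ever joins an
    inside node to an outside node.
    """
    if decomposition is None:
        decomposition = clusters.subtree_roots
    sizes = clusters.cluster_sizes()
    label: dict[int, str] = {}
    cluster_of: dict[int, int] = {}
    for u in tree.adj:
        if tree.is_tip(u):
            cid = clusters.tip_to_cluster.get(tree.taxon_of[u])
            if cid is None:
                raise ValueError(f"tip {tree.taxon_of[u]!r} not covered by "
                                 "the cluster assignment")
            cluster_of[u] = cid
            label[u] = BOUNDARY if sizes[cid] == 1 else OUTSIDE
        else:
            label[u] = INSIDE

    for parent_dir, root in decomposition:
        if tree.is_tip(root):
            continue
        for u, parent in tree.postorder_from(root, exclude=parent_dir):
            p = parent if parent is not None else parent_dir
            if tree.is_tip(u):
                continue
            kids = [v for v in sorted(tree.adj[u]) if v != p]
            lk = [label[v] for v in kids]
            if all(l in (INSIDE, BOUNDARY) for l in lk):
                label[u] = INSIDE
            elif OUTSIDE in lk and any(l in (INSIDE, BOUNDARY) for l in lk):
                label[u] = INSIDE
                for v in kids:
                    if label[v] == OUTSIDE:
                        label[v] = BOUNDARY
            else:  # both outside
                ca, cb = cluster_of[kids[0]], cluster_of[kids[1]]
                if ca == cb:
                    label[u] = OUTSIDE
                    cluster_of[u] = ca
                else:
                    label[u] = INSIDE
                    label[kids[0]] = BOUNDARY
                    label[kids[1]] = BOUNDARY
        # consistency at the subtree root: if the whole subtree collapsed
        # into one cluster the root itself becomes the virtual tip, so the
        # edge toward the rest of the backbone never joins inside to outside
        if label[root] == OUTSIDE:
            label[root] = BOUNDARY
    return BackboneLabels(label, cluster_of)


def count_backbone_tips(labels: BackboneLabels) -> int:
    """Number of boundary nodes: real tips kept plus virtual tips."""
    return len(labels.boundary_nodes())


def induced_subtree(tree: Tree, nodes: set[int]) -> Tree:
    """Subgraph of `tree` induced by `nodes`, keeping node ids, branch
    lengths and taxon labels.  The caller guarantees connectedness."""
    sub = Tree()
    sub.adj = {u: {v: b for v, b in tree.adj[u].items() if v in nodes}
               for u in nodes}
    sub.taxon_of = {u: t for u, t in tree.taxon_of.items() if u in nodes}
    sub.node_of_taxon = {t: u for u, t in sub.taxon_of.items()}
    sub._next_id = tree._next_id
    return sub


def extract_backbone(tree: Tree, labels: BackboneLabels, engine
                     ) -> tuple[Tree, dict[int, object]]:
    """Reduce the comprehensive tree to its backbone.

    Returns the induced backbone tree (inside + boundary nodes; boundary
    nodes become leaves) and `leaf_data` mapping each boundary node that
    is an ancestral node to the conditional vector of its excluded clade,
    computed by `engine` on the comprehensive tree.  An engine constructed
    on the reduced tree with this leaf_data computes the log likelihood of
    the comprehensive tree.
    """
    nodes = labels.backbone_nodes()
    backbone = induced_subtree(tree, nodes)
    for u in nodes:
        if not backbone.adj[u]:
            raise RuntimeError("disconnected backbone (labeling bug)")
    leaf_data: dict[int, object] = {}
    for b in labels.boundary_nodes():
        if tree.is_tip(b):
            continue
        neighbors = [v for v in tree.adj[b] if v in nodes]
        if len(neighbors) != 1:
            raise RuntimeError(f"boundary node {b} has {len(neighbors)} "
                               "backbone neighbors")
        leaf_data[b] = engine.conditional(b, neighbors[0])
    return backbone, leaf_data
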