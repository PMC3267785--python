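"""Unrooted binary phylogenies with branch lengths.

The tree is stored as an adjacency map over integer node ids.  Tips carry
taxon labels and have degree 1; inner nodes are unlabeled degree-3
junctions.  An unrooted binary tree on n >= 3 taxa has n tips, n - 2 inner
nodes and 2n - 3 edges.  All traversal-based operations accept an arbitrary
rooting (at a node or along an edge); likelihood invariance under the
choice of rooting is a property of reversible models, not of this class.
"""

from __future__ import annotations

from collections import deque
from typing import Iterable, Iterator, Sequence

__all__ = [
    "Tree",
    "NewickError",
    "TreeError",
    "parse_newick",
    "write_newick",
    "robinson_foulds",
]


class TreeError(ValueError):
    pass


class NewickError(ValueError):
    """Malformed Newick input; carries the character offset of the error."""

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


class Tree:
    """Unrooted binary tree with non-negative branch lengths."""

    def __init__(self) -> None:
        self.adj: dict[int, dict[int, float]] = {}
        self.taxon_of: dict[int, str] = {}
        self.node_of_taxon: dict[str, int] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, taxon: str | None = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if taxon is not None:
            if taxon in self.node_of_taxon:
                raise TreeError(f"duplicate taxon label {taxon!r}")
            self.taxon_of[nid] = taxon
            self.node_of_taxon[taxon] = nid
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if length < 0 or not length == length or length in (float("inf"),):
            raise TreeError(f"branch length must be finite and >= 0, got {length}")
        self.adj[u][v] = length
        self.adj[v][u] = length

    def remove_edge(self, u: int, v: int) -> None:
        del self.adj[u][v]
        del self.adj[v][u]

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        taxon = self.taxon_of.pop(u, None)
        if taxon is not None:
            del self.node_of_taxon[taxon]

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nb) for u, nb in self.adj.items()}
        t.taxon_of = dict(self.taxon_of)
        t.node_of_taxon = dict(self.node_of_taxon)
        t._next_id = self._next_id
        return t

    # -- queries -------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.taxon_of)

    def tips(self) -> list[int]:
        return sorted(self.taxon_of)

    def taxa(self) -> list[str]:
        return sorted(self.node_of_taxon)

    def inner_nodes(self) -> list[int]:
        return sorted(u for u in self.adj if u not in self.taxon_of)

    def nodes(self) -> list[int]:
        return sorted(self.adj)

    def is_tip(self, u: int) -> bool:
        return u in self.taxon_of

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u in sorted(self.adj):
            for v, b in self.adj[u].items():
                if u < v:
                    out.append((u, v, b))
        return out

    def branch_length(self, u: int, v: int) -> float:
        return self.adj[u][v]

    def set_branch_length(self, u: int, v: int, b: float) -> None:
        self.adj[u][v] = b
        self.adj[v][u] = b

    def total_length(self) -> float:
        return sum(b for _, _, b in self.edges())

    def validate(self) -> None:
        n = self.n_tips
        if n < 3:
            raise TreeError(f"unrooted binary tree needs >= 3 tips, got {n}")
        for u in self.adj:
            d = self.degree(u)
            if self.is_tip(u):
                if d != 1:
                    raise TreeError(f"tip node {u} has degree {d}")
            elif d != 3:
                raise TreeError(f"inner node {u} has degree {d} (binary expected)")
        n_inner = len(self.adj) - n
        if n_inner != n - 2:
            raise TreeError(f"expected {n - 2} inner nodes, found {n_inner}")

    # -- traversal -----------------------------------------------------

    def postorder_from(self, root: int, exclude: int | None = None
                       ) -> list[tuple[int, int | None]]:
        """(node, parent) pairs in post-order, rooted at `root`.

        `exclude` blocks the traversal from crossing the edge
        (root, exclude), which roots the traversal on a directed edge.
        """
        order: list[tuple[int, int | None]] = []
        stack: list[tuple[int, int | None]] = [(root, exclude)]
        seen: list[tuple[int, int | None]] = []
        while stack:
            u, parent = stack.pop()
            seen.append((u, parent))
            for v in sorted(self.adj[u]):
                if v != parent:
                    stack.append((v, u))
        for u, parent in reversed(seen):
            order.append((u, parent if parent != exclude or u != root else None))
        # root's recorded parent is the excluded neighbor; normalize to None
        return [(u, (None if u == root else p)) for u, p in order]

    def subtree_tips(self, u: int, parent: int) -> list[int]:
        """Tips in the subtree on the u side of edge (parent, u)."""
        out = []
        stack = [(u, parent)]
        while stack:
            x, p = stack.pop()
            if self.is_tip(x):
                out.append(x)
            for y in self.adj[x]:
                if y != p:
                    stack.append((y, x))
        return sorted(out)

    # -- distances -----------------------------------------------------

    def distances_from(self, source: int) -> dict[int, float]:
        dist = {source: 0.0}
        dq = deque([source])
        while dq:
            u = dq.popleft()
            for v, b in self.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + b
                    dq.append(v)
        return dist

    def patristic_distance(self, a: str, b: str) -> float:
        for t in (a, b):
            if t not in self.node_of_taxon:
                raise TreeError(f"unknown taxon {t!r}")
        if a == b:
            return 0.0
        return self.distances_from(self.node_of_taxon[a])[self.node_of_taxon[b]]

    def patristic_matrix(self, taxa: Sequence[str] | None = None):
        """Symmetric patristic distance matrix; one traversal per tip."""
        import numpy as np

        if taxa is None:
            taxa = self.taxa()
        taxa = list(taxa)
        if not taxa:
            raise TreeError("empty taxon subset")
        nodes = []
        for t in taxa:
            if t not in self.node_of_taxon:
                raise TreeError(f"unknown taxon {t!r}")
            nodes.append(self.node_of_taxon[t])
        m = np.zeros((len(taxa), len(taxa)))
        for i, src in enumerate(nodes):
            dist = self.distances_from(src)
            for j, dst in enumerate(nodes):
                m[i, j] = dist[dst]
        # path sums accumulated from either end can differ in the last ulp;
        # mirror the upper triangle so the matrix is exactly symmetric
        m = np.triu(m) + np.triu(m, 1).T
        np.fill_diagonal(m, 0.0)
        return taxa, m

    # -- subtree lengths ----------------------------------------------

    def subtree_length(self, u: int, v: int) -> float:
        """Sum of branch lengths in the subtree on the v side of edge (u, v),
        including the attaching branch (u, v) itself.

        With this convention the three directed subtrees at any inner node i
        partition the edge set, so stl(T_i,a) + stl(T_i,b) + stl(T_i,c)
        equals the total tree length exactly.
        """
        total = self.adj[u][v]
        stack = [(v, u)]
        while stack:
            x, p = stack.pop()
            for y, b in self.adj[x].items():
                if y != p:
                    total += b
                    stack.append((y, x))
        return total

    def all_directed_subtree_lengths(self) -> dict[tuple[int, int], float]:
        """stl for every directed edge (u, v) in O(edges) via two passes."""
        root = next(iter(self.adj))
        order = self.postorder_from(root)
        down: dict[tuple[int, int], float] = {}
        for u, parent in order:
            if parent is None:
                continue
            s = self.adj[parent][u]
            for v in self.adj[u]:
                if v != parent:
                    s += down[(u, v)]
            down[(parent, u)] = s
        # pre-order pass: stl of the subtree seen from v looking back through u
        up: dict[tuple[int, int], float] = {}
        stack: list[tuple[int, int | None]] = [(root, None)]
        while stack:
            u, parent = stack.pop()
            for v in self.adj[u]:
                if v == parent:
                    continue
                s = self.adj[u][v]
                for w in self.adj[u]:
                    if w != v and w != parent:
                        s += down[(u, w)]
                if parent is not None:
                    s += up[(u, parent)]
                up[(v, u)] = s
                stack.append((v, u))
        result = dict(down)
        result.update(up)
        return result

    # -- bipartitions / RF --------------------------------------------

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized to the side not
        containing the lexicographically smallest taxon."""
        ref = min(self.node_of_taxon)
        parts: set[frozenset[str]] = set()
        for u, v, _ in self.edges():
            if self.is_tip(u) or self.is_tip(v):
                continue
            side = frozenset(self.taxon_of[t] for t in self.subtree_tips(v, u))
            if ref in side:
                side = frozenset(self.taxa()) - side
            parts.add(side)
        return parts


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Symmetric-difference (RF) distance between two resolved unrooted
    trees on the same taxon set: the number of non-trivial bipartitions
    present in exactly one of the two topologies."""
    if a.taxa() != b.taxa():
        raise TreeError("taxon sets differ")
    return len(a.bipartitions() ^ b.bipartitions())


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted binary Tree.

    A rooted top-level bifurcation is collapsed into a single edge whose
    length is the sum of the two child edges.  Missing branch lengths are
    read as 0.  Multifurcations (other than an unrooted trifurcation at the
    top level) are rejected.
    """
    tree = Tree()
    s = text.strip()
    pos = 0

    def error(msg: str) -> NewickError:
        return NewickError(msg, pos)

    def parse_clade() -> tuple[int, float]:
        nonlocal pos
        if pos >= len(s):
            raise error("unexpected end of input")
        if s[pos] == "(":
            pos += 1
            children = [parse_clade()]
            while pos < len(s) and s[pos] == ",":
                pos += 1
                children.append(parse_clade())
            if pos >= len(s) or s[pos] != ")":
                raise error("expected ')'")
            pos += 1
            label, length = parse_label_length()
            if label:
                raise error("inner-node labels are not supported")
            node = tree.new_node()
            for child, bl in children:
                tree.add_edge(node, child, bl)
            return node, length
        label, length = parse_label_length()
        if not label:
            raise error("expected taxon label")
        return tree.new_node(label), length

    def parse_label_length() -> tuple[str, float]:
        nonlocal pos
        start = pos
        while pos < len(s) and s[pos] not in ",():;":
            pos += 1
        label = s[start:pos].strip()
        length = 0.0
        if pos < len(s) and s[pos] == ":":
            pos += 1
            lstart = pos
            while pos < len(s) and s[pos] not in ",();":
                pos += 1
            try:
                length = float(s[lstart:pos])
            except ValueError:
                raise NewickError(f"bad branch length {s[lstart:pos]!r}", lstart)
        return label, length

    if not s or s[0] != "(":
        raise NewickError("tree must start with '('", 0)
    root, _ = parse_clade()
    if pos < len(s) and s[pos] == ";":
        pos += 1
    if s[pos:].strip():
        raise error("trailing characters after ';'")

    deg = tree.degree(root)
    if deg == 2:
        (u, bu), (v, bv) = tree.adj[root].items()
        tree.remove_node(root)
        tree.add_edge(u, v, bu + bv)
    elif deg != 3:
        raise NewickError(f"top-level node has {deg} children; expected 2 or 3", 0)
    try:
        tree.validate()
    except TreeError as exc:
        raise TreeError(f"not a valid unrooted binary tree: {exc}") from exc
    return tree


def _format_length(b: float) -> str:
    # 17 significant digits: doubles survive the round trip exactly
    return f"{b:.17g}"


def write_newick(tree: Tree, root_at: int | tuple[int, int] | None = None) -> str:
    """Deterministic Newick output.

    Children are ordered by the smallest taxon label contained in their
    subtree; branch lengths are printed with 12 significant digits.
    `root_at` may be an inner node (trifurcation at the top level) or an
    edge (u, v) (top-level bifurcation splitting that branch halfway).
    By default the tree is rooted at the inner node adjacent to the
    lexicographically smallest taxon.
    """
    tree.validate()

    def min_taxon(u: int, parent: int) -> str:
        return min(tree.taxon_of[t] for t in tree.subtree_tips(u, parent))

    def render(u: int, parent: int, b: float) -> str:
        if tree.is_tip(u):
            return f"{tree.taxon_of[u]}:{_format_length(b)}"
        kids = sorted(
            ((v, bl) for v, bl in tree.adj[u].items() if v != parent),
            key=lambda vb: min_taxon(vb[0], u),
        )
        inner = ",".join(render(v, u, bl) for v, bl in kids)
        return f"({inner}):{_format_length(b)}"

    if isinstance(root_at, tuple):
        u, v = root_at
        b = tree.adj[u][v]
        left = render(u, v, b / 2.0)
        right = render(v, u, b / 2.0)
        if min_taxon(u, v) > min_taxon(v, u):
            left, right = right, left
        return f"({left},{right});"
    if root_at is None:
        smallest = tree.node_of_taxon[min(tree.node_of_taxon)]
        root_at = next(iter(tree.adj[smallest]))
    if tree.is_tip(root_at):
        root_at = next(iter(tree.adj[root_at]))
    kids = sorted(tree.adj[root_at].items(), key=lambda vb: min_taxon(vb[0], root_at))
    inner = ",".join(render(v, root_at, bl) for v, bl in kids)
    return f"({inner});"
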