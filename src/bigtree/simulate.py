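"""Synthetic data: Yule trees, GTR+Gamma sequences, block-missing data.

The generator emulates multi-gene phylogenomic alignments: substitutions
only (no indel process), with structured missingness injected per
(taxon, gene) block — a taxon either has a gene or contributes an all-gap
block for it, which is the regime in which gap-aware subtree equality
vectors pay off.  Site rates are drawn from the continuous Gamma(alpha,
alpha) distribution, so the inference-side discretization remains a
genuine approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .model import GTRParams, jc_params
from .tree import Tree

__all__ = [
    "SimulationSpec",
    "simulate_tree",
    "caterpillar_tree",
    "simulate_alignment",
    "inject_structured_gaps",
    "run_backbone_experiment",
]

DEFAULT_GTR = GTRParams((1.2, 3.0, 0.8, 0.9, 3.2, 1.0),
                        (0.30, 0.21, 0.24, 0.25))


@dataclass
class SimulationSpec:
    """Study conditions for a synthetic multi-gene dataset."""

    n: int = 64
    sites: int = 300
    genes: int = 6
    presence_prob: float = 1.0
    params: GTRParams = field(default_factory=lambda: DEFAULT_GTR)
    alpha: float = 0.7
    seed: int = 1
    scale: float = 1.0
    mean_branch_length: float = 0.08


def simulate_tree(n: int, seed: int, scale: float = 1.0,
                  mean_branch_length: float = 0.08,
                  target_total_length: float | None = None) -> Tree:
    """Random unrooted binary tree with a Yule topology.

    Topology: starting from the 3-tip star, a uniformly chosen tip is
    repeatedly split into a cherry (the Yule speciation process).  Branch
    lengths are i.i.d. exponential with the given mean, multiplied by
    `scale`, or rescaled so the total tree length equals
    `target_total_length` when that is given.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    tree = Tree()
    center = tree.new_node()
    leaves = []
    for _ in range(3):
        leaf = tree.new_node()
        tree.add_edge(center, leaf, 0.0)
        leaves.append(leaf)
    while len(leaves) < n:
        i = int(rng.integers(len(leaves)))
        split = leaves[i]
        a = tree.new_node()
        b = tree.new_node()
        tree.add_edge(split, a, 0.0)
        tree.add_edge(split, b, 0.0)
        leaves[i] = a
        leaves.append(b)
    width = len(str(n))
    for idx, leaf in enumerate(sorted(leaves)):
        taxon = f"T{idx:0{width}d}"
        tree.taxon_of[leaf] = taxon
        tree.node_of_taxon[taxon] = leaf
    lengths = rng.exponential(mean_branch_length, size=len(tree.edges())) * scale
    if target_total_length is not None:
        lengths *= target_total_length / lengths.sum()
    for (u, v, _), b in zip(tree.edges(), lengths):
        tree.set_branch_length(u, v, float(b))
    tree.validate()
    return tree


def caterpillar_tree(n: int, branch_length: float = 0.1) -> Tree:
    """Fully pectinate (ladder) tree: the deep-path worst case for
    numerical underflow of unscaled conditional likelihoods."""
    if n < 3:
        raise ValueError("need n >= 3")
    width = len(str(n))
    tree = Tree()
    spine = tree.new_node()
    tree.add_edge(spine, tree.new_node(f"T{0:0{width}d}"), branch_length)
    tree.add_edge(spine, tree.new_node(f"T{1:0{width}d}"), branch_length)
    for i in range(2, n - 1):
        nxt = tree.new_node()
        tree.add_edge(spine, nxt, branch_length)
        tree.add_edge(nxt, tree.new_node(f"T{i:0{width}d}"), branch_length)
        spine = nxt
    tree.add_edge(spine, tree.new_node(f"T{n - 1:0{width}d}"), branch_length)
    tree.validate()
    return tree


def simulate_alignment(tree: Tree, params: GTRParams, alpha: float | None,
                       length: int, seed: int) -> Alignment:
    """Evolve DNA sequences along the tree under GTR(+continuous Gamma).

    Root states are drawn from the stationary frequencies pi; each site
    gets a continuous Gamma(alpha, alpha) rate (rate 1 when alpha is
    None); states propagate edge-wise through P(b * r_site).
    """
    rng = np.random.default_rng(seed)
    pi = params.pi
    lam, right, left = params.eigensystem()
    if alpha is None:
        site_rates = np.ones(length)
    else:
        site_rates = rng.gamma(alpha, 1.0 / alpha, size=length)
    root = tree.inner_nodes()[0]
    states: dict[int, np.ndarray] = {
        root: rng.choice(4, size=length, p=pi)
    }
    order = list(reversed(tree.postorder_from(root)))  # pre-order
    for u, parent in order:
        if parent is None:
            continue
        b = tree.adj[parent][u]
        expo = np.exp(np.outer(site_rates * b, lam))  # (S, 4)
        P = np.einsum("ab,sb,bc->sac", right, expo, left, optimize=False)
        P = np.clip(P, 0.0, None)
        P /= P.sum(axis=2, keepdims=True)
        rows = P[np.arange(length), states[parent]]  # (S, 4)
        u01 = rng.random(length)
        states[u] = (rows.cumsum(axis=1) < u01[:, None]).sum(axis=1).clip(0, 3)
    alphabet = np.array(list("ACGT"))
    taxa = tree.taxa()
    seqs = ["".join(alphabet[states[tree.node_of_taxon[t]]]) for t in taxa]
    return Alignment(taxa, seqs)


def inject_structured_gaps(aln: Alignment, blocks, presence_prob: float,
                           seed: int, ensure_one_gene: bool = True
                           ) -> tuple[Alignment, float]:
    """Blank whole gene blocks per taxon with probability 1 - presence_prob.

    `blocks` is either a list of block lengths summing to the site count
    or an integer number of (near-)equal blocks.  Every taxon keeps at
    least one gene when `ensure_one_gene` (an all-gap taxon carries no
    signal at all).  Returns the gapped alignment and its realized
    gappyness (fraction of gap characters).
    """
    sites = aln.site_count
    if isinstance(blocks, int):
        base = sites // blocks
        lens = [base + (1 if i < sites % blocks else 0) for i in range(blocks)]
    else:
        lens = list(blocks)
    if sum(lens) != sites:
        raise ValueError(f"block lengths sum to {sum(lens)}, expected {sites}")
    bounds = np.concatenate([[0], np.cumsum(lens)])
    rng = np.random.default_rng(seed)
    out = []
    for seq in aln.sequences:
        present = rng.random(len(lens)) < presence_prob
        if ensure_one_gene and not present.any():
            present[int(rng.integers(len(lens)))] = True
        chars = list(seq)
        for g, keep in enumerate(present):
            if not keep:
                chars[bounds[g]:bounds[g + 1]] = "-" * lens[g]
        out.append("".join(chars))
    gapped = Alignment(list(aln.taxa), out)
    return gapped, gapped.gappyness()


def simulate_dataset(spec: SimulationSpec) -> tuple[Tree, Alignment, float]:
    """Tree + gapped alignment + realized gappyness for a SimulationSpec."""
    tree = simulate_tree(spec.n, spec.seed, spec.scale,
                         spec.mean_branch_length)
    aln = simulate_alignment(tree, spec.params, spec.alpha, spec.sites,
                             spec.seed + 1)
    if spec.presence_prob < 1.0:
        aln, gappyness = inject_structured_gaps(aln, spec.genes,
                                                spec.presence_prob,
                                                spec.seed + 2)
    else:
        gappyness = aln.gappyness()
    return tree, aln, gappyness


def run_backbone_experiment(spec: SimulationSpec, R_values, seeds,
                            spr_radius: int = 10, tol: float = 0.5,
                            max_cycles: int = 8):
    """Backbone-vs-full search replication on one simulated dataset.

    For every (R, starting-tree seed) pair a search is run from the same
    parsimony starting tree; rows report the final GTR+Gamma score of the
    comprehensive tree, Robinson-Foulds distances to the true tree and to
    the matched full search (R = 1), and the number of SPR cycles.
    """
    import pandas as pd

    from .alignment import compress_patterns
    from .search import SearchConfig, backbone_search
    from .tree import robinson_foulds

    true_tree, aln, _ = simulate_dataset(spec)
    paln = compress_patterns(aln)
    rows = []
    full_trees: dict[int, Tree] = {}
    R_values = list(R_values)
    if 1.0 not in R_values:
        R_values = R_values + [1.0]
    for seed in seeds:
        for R in sorted(R_values, reverse=True):  # full search first
            config = SearchConfig(seed=seed, R=R, spr_radius=spr_radius,
                                  tol=tol, max_cycles=max_cycles)
            final, trace = backbone_search(paln, config)
            if R == 1.0:
                full_trees[seed] = final
            rows.append({
                "R": R,
                "seed": seed,
                "lnl": trace.final_lnl,
                "rf_true": robinson_foulds(final, true_tree),
                "rf_full": robinson_foulds(final, full_trees[seed]),
                "cycles": len(trace.cycle_lnl),
            })
    return pd.DataFrame(rows, columns=["R", "seed", "lnl", "rf_true",
                                       "rf_full", "cycles"])
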