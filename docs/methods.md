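# Methods

This note documents the models, numerical choices and design decisions
behind `bigtree`, and what the synthetic-data experiments do and do not
demonstrate.

## Likelihood model

Sequences evolve under the general time-reversible (GTR) model. The
generator Q is built from six exchangeabilities (G↔T fixed to 1 for
identifiability) and stationary frequencies π, and is normalized so that
−Σ π_i Q_ii = 1; branch lengths are therefore expected substitutions per
site. Transition matrices P(b·r) = exp(Q·b·r) come from the symmetric
eigendecomposition of diag(√π) Q diag(1/√π), computed once per parameter
set and cached.

Rate heterogeneity uses the discrete Γ(α, α) approximation with K
equiprobable categories (default K = 4). Category rates are the
conditional means of the quantile bins — not the medians — because bin
means preserve a mean rate of exactly 1, which the CAT comparison
(tree-length ratios, branch-length correlations) presupposes. A median
variant, rescaled to mean 1, is available behind a flag.

Gaps, `?` and `N` all map to the full state set {A,C,G,T}: an
undetermined character constrains nothing, so these are mathematically
interchangeable in the likelihood. Other IUPAC codes map to their partial
state sets. Alignments are compressed to distinct site patterns with
integer weights before any likelihood work; pattern order is
first-occurrence order, and the final accumulation Σ_c w_c log ℓ(c) uses
that fixed order, so alternative kernels can be compared bit for bit.

### Numerical scaling

Every pattern of an ancestral vector holds K×4 conditional values. When
*all* of them fall below ε = 2⁻²⁵⁶, all are multiplied by 2²⁵⁶ and the
pattern's integer scaling count is incremented; children's counts add on
combination, tips implicitly carry count 0, and the root reverses the
accumulated counts as (U_i + U_j)·log ε. Scaling must be joint across the
K rate categories: per-category scaling cannot be undone stably at the
root because the per-category magnitudes diverge. That divergence is also
the failure mode of the Γ model on very deep trees — when the largest and
smallest of the K×4 values no longer fit the double range together, no
joint factor works, and the engine raises a typed underflow error
(`LikelihoodUnderflowError`) advising a per-site-rate model rather than
silently returning −inf. The alternative scale-largest-to-1 policy (fractional scaling counts on
the same log-epsilon scale, reversed identically at the root) is
available via `GammaEngine(..., scaling_policy="largest-to-one")` for
numerics experiments but is not the default.

The scaled computation is validated against an arbitrary-precision
(mpmath) recursion on 500-tip ladder trees where the unscaled double
computation demonstrably underflows to zero; agreement is at ~1e-15
relative, far inside the 1e-8 requirement.

### Branch-length and model optimization

Branch lengths are optimized by sweeps: per sweep, conditional vectors on
both sides of every edge are computed once (one downward and one upward
pass), then each branch is optimized by bounded scalar minimization
(Brent) of the per-edge likelihood on [1e-8, 10]. A sweep that fails to
improve the total is rolled back, so the reported likelihood never
decreases; sweeps stop when the improvement falls below `tol` (default
0.1 log units). Brent was chosen over Newton–Raphson deliberately: it
needs no derivatives, cannot overshoot, and converges unconditionally on
the bracket; the exact optimization schedule is a design choice of this
package. Model parameters (5 free exchangeabilities, α, optionally
frequency logits) are optimized coordinate-wise with the same scalar
optimizer on log scales; frequencies default to empirical counts.
Zero-length input branches are clamped to 1e-8 before likelihood work
(logged once).

## Subtree Equality Vectors

The gap variant tracks only all-gap subtree patterns: one bit per
pattern per node, with parent = AND of children. All-gap patterns share
one "signal" column per node (their conditional value cannot depend on
the pattern), so both the arithmetic and, in memory-saving mode, the
storage for those patterns are skipped. The SEV kernel calls the same
primitive kernels on the same values in the same order as the dense
kernel, making the per-pattern results — and hence the total — bit
identical; this identity is asserted over a 50-fixture grid spanning
0–90% gappyness.

Scaling counts of skipped patterns are carried by the signal column's own
count: an all-gap subtree column is uniform at the tips, so its value and
its scaling history depend only on subtree topology and branch lengths.
This bookkeeping is validated by the bit-exact identity rather than
derived from first principles.

Memory accounting: a node stores (patterns − popcount + 1) columns; the
dynamic reallocation policy (reallocate only when the popcount changes
after a topology change or rerooting) is modeled by an
allocation-counting abstraction so the contract is testable without
memory-level assertions.

Kernel auto-selection times one full traversal per kernel (best of 3 on a
monotonic clock) and picks SEV only when it is ≥20% faster. Whether SEV
wins is regime-dependent: with gene presence drawn i.i.d. per
(taxon, gene) — this generator's default — all-gap regions AND away
within a few levels above the tips (at 80% gappyness the mean inner-node
all-gap fraction is only ~32%), and in this vectorized implementation the
bookkeeping overhead then cancels the savings, so the standard kernel is
correctly selected. When missingness is phylogenetically clustered, as in
real multi-gene supermatrices where related taxa share sequenced genes,
most inner-node patterns are all-gap and the SEV traversal wins; the test
suite constructs such a clade-structured fixture. Speedups are therefore
reported, not asserted, except through the selection contract itself.

## Backbone construction and search

The backbone pipeline: (1) find the innermost node, by default the inner
node maximizing total length minus its largest directed subtree length
(alternatives — minimum stl variance, minimum node-to-tip distance
variance, maximum minimal node-to-tip distance — sit behind a selector;
ties break to the lowest node id); (2) depth-first decomposition into
subtrees of ≤ m tips (default 1024), which bounds every partial patristic
matrix at O(m²); (3) per-subtree cluster budgets c̄_i = ⌊1/2 + c·n_i/n⌋
with the overhead/deficit distributed proportionally and then settled ±1
in decreasing-subtree-size order (the raw proportional iteration has no
termination guarantee; this deterministic variant always terminates and
reproduces the worked 15,000/5,000 example); (4) average-linkage
clustering (scipy) of each partial matrix, tips sorted lexicographically
for determinism, cut by undoing the last c_i − 1 merges so exactly c_i
clusters always result.

A directed subtree's length stl includes its attaching branch; with this
convention the three stl values at any inner node sum exactly to the
total tree length, which is the identity the innermost-node criterion
relies on.

Labeling starts with inner nodes inside, singleton-cluster tips boundary,
other tips outside, then post-order from each decomposition root: a
same-cluster pair of outside children propagates outside upward; a
cluster conflict promotes the parent to inside and both children to
boundary; mixed children promote the outside child to boundary. A
subtree root still labeled outside after the pass — its entire subtree
is one cluster — becomes a boundary virtual tip itself, so no edge ever
joins inside to outside. A non-monophyletic cluster necessarily produces
≥2 boundary nodes, so the realized backbone tip count is ≥ c, with
equality exactly when every cluster is monophyletic.

Virtual-tip conditional vectors are recomputed from the comprehensive
tree whenever the backbone is rebuilt (no caching) — simpler and always
correct. The likelihood of the comprehensive tree evaluated through
virtual tips equals the standard evaluation to ~1e-15 relative.

The search protocol: randomized stepwise-addition parsimony starting tree
(Fitch-scored insertions, seed-shuffled order, 0.1 starting branch
lengths), model + branch optimization on the comprehensive tree, then
cycles of lazy SPR restricted to the backbone. Lazy scoring combines the
pruned subtree's vector with precomputed per-edge vectors of the
remainder tree, splitting the insertion branch halfway — O(patterns) per
candidate. The best candidate per prune is verified: the move is applied,
the three junction branches are re-optimized, and the move is kept only
if the comprehensive score strictly improves, so traces are monotone.
Reinsertion into the edge created by the prune (a topology no-op) is
excluded. After each cycle all branch lengths are re-optimized and the
backbone rebuilt from the current best tree; the loop stops when a cycle
improves the score by under `tol` (default 0.5 log units) or after
`max_cycles`. With R = 1 the same code performs an unrestricted full
search. Candidate order and tie-breaks are fixed, so (alignment, config)
fully determines the output.

## Synthetic data and study conditions

Trees are Yule: starting from the 3-tip star, a uniform random tip is
repeatedly split (cherry counts match the n/3 Yule expectation). Branch
lengths are i.i.d. exponential with mean 0.08 by default — typical for
multi-gene plant matrices — optionally rescaled to a target tree length.
Sequences evolve site-independently under GTR with *continuous* Γ rates,
so the inference-side discretization stays a genuine approximation; there
is no indel process (missingness is injected as per-gene blocks, which is
the structure the SEV and memory claims concern). Gene presence is an
i.i.d. per-(taxon, gene) coin flip; each taxon keeps at least one gene.
The ~81% gappyness regime of large plant supermatrices is reachable
(6 genes at presence ≈ 0.19).

Experiment sizes were fixed up front as desk-scale choices: the search
comparison uses 64 taxa × 300 sites × α = 0.7 with three parsimony
seeds and R ∈ {0.25, 0.5, 1}; the CAT–Γ comparison uses 20 candidate
trees (the true tree plus successive random SPR perturbations) on
100 taxa × 500 sites, K = 25. These echo the structure — not the absolute
values — of the large-tree experiments the techniques were designed for:
absolute likelihoods, runtimes and memory totals of 38K/56K-taxon runs
are out of scope at desk scale.

What the simulations show — and what they cannot. Passing the SEV
identity grid shows kernel equivalence under block-structured
missingness, not performance on real supermatrices. The CAT correlations
(Pearson and Spearman ≥ 0.9 expected on this synthetic collection) echo
the qualitative finding that CAT and Γ rank trees almost identically;
the printed correlations of the large empirical datasets are
dataset-specific. The backbone comparison shows that R = 0.5 searches
finish within a few log units of matched full searches; at R = 0.25 the
restriction can freeze starting-tree errors inside clusters and the gap
to the full search can exceed 5 log units on some seeds — consistent
with the original finding that aggressive reduction trades likelihood
for speed and that R > 0.25 is the safe regime.

## Known limitations

- DNA only; no protein or codon models, no partitioned branch lengths.
- The per-site categorization heuristic is this package's own
  (quantile-initialized weighted k-means on log rates); it is validated
  by the lossless K = #distinct-rates oracle, not by equivalence to any
  other implementation.
- Lazy SPR verification re-evaluates the full tree per accepted move;
  at desk scale this is cheap, but it is not the constant-work update a
  production C implementation would use.
- The SEV speed advantage requires phylogenetically clustered
  missingness and large pattern counts; on small or i.i.d.-gapped data
  the auto-selector correctly prefers the standard kernel.
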