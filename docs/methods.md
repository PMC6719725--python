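# Methods

This note documents the models and procedures implemented in `modulekit`,
the parameters that matter, the numerical choices made where the design was
open, and what the synthetic benchmarks do and do not establish.

## Networks and module validity

Networks are weighted, optionally directed, with positive confidence-like
weights. Duplicate records of an undirected edge keep the maximum weight
(confidence aggregation); self-loops are rejected on input and only appear
internally (resistance augmentation, MCL convention). All clustering
methods operate on the canonical (lexicographic) node ordering, which makes
every pipeline invariant to the order of edges in the input file.

Module sets obey two validity rules throughout: modules are pairwise
disjoint, and after finalization each has between `min_size = 3` and
`max_size = 100` genes. Oversize clusters are split recursively by the
producing method; undersize clusters are dropped. Modules need not cover
all genes.

Preprocessing utilities shared by the methods: weight-threshold and
quantile sparsification (ties at the threshold are all kept, so the result
is order-independent and idempotent), optional min–max weight rescaling
(off by default — the DSD method runs on raw networks), and, for directed
networks, strong-connectivity augmentation that adds a reciprocal edge of
weight `min_weight / 100` wherever one is missing, making the random walk
irreducible without materially distorting flow.

## Diffusion state distance spectral clustering

For a connected network with row-stochastic walk operator `P = D⁻¹A`
(steps proportional to edge weight), the t-step visit-count profile is
`He^t = Σ_{s=0..t} P^s` (the walk counts its starting point, so `t = 0`
gives the identity and each row sums to `t + 1`). The diffusion state
distance is the L1 distance between profile rows and converges as
`t → ∞` to

    DSD(x, y) = ||(1_x − 1_y)(I − P + W)⁻¹||₁

where every row of `W` is the degree distribution π. The implementation
computes the resolvent by a dense solve — exact at the network sizes the
test benchmarks use; the convergence of the walk-based definition to this
closed form requires an aperiodic (non-bipartite) graph, which molecular
networks are in practice.

The DSD matrix is mapped to a similarity kernel `S = exp(−DSD²/(2σ²))`.
σ defaults to the median off-diagonal distance — a standard scale-free
bandwidth choice that pins the median similarity at `exp(−1/2)`; it is
overridable. The kernel is clustered with normalized spectral clustering
(spectral embedding + k-means, 10 restarts, fixed seed). `k` is the only
free parameter; the default `k = round(n/40)` reflects a typical module
granularity of a few dozen genes and should be tuned per application.
Clusters above `max_size` are split recursively with `k = 2` on the kernel
restricted to the cluster (restriction, rather than re-deriving DSD on the
induced subgraph, keeps the recursion deterministic and cheap). Each
connected component is processed separately — DSD is only defined within a
component — with the `k` budget allocated proportionally to component size.

## Resistance modularity

On the augmented adjacency `A' = A + rI` with node strengths
`s_i = deg_i + r` and total ordered-pair weight `2m' = 2m + nr`,

    Q(r) = Σ_c [ (2 w_c + r n_c) / 2m' − (s_c / 2m')² ].

Each self-loop counts once, inside its own community — the convention under
which `Q(0)` is exactly standard weighted modularity (verified against an
independent implementation). The resistance raises every node's
contribution to its own community's internal strength, so larger `r` yields
smaller communities; `r` may be negative as long as all augmented strengths
stay positive.

The optimizer combines fast greedy agglomeration (merge the community pair
with the best Q gain; ties broken by the lexicographically smallest pair)
with fine-tuning by single-node repositioning, alternating the two passes
to a fixed point. Because single-node moves alone stall in shallow local
maxima on weighted graphs, the search restarts 10 times: once from the
deterministic greedy path and otherwise from seeded random initial
groupings and sweep orders, keeping the best Q. On 7-node graphs this
reliably attains the brute-force maximum over all partitions; at a few
hundred nodes a run takes well under a second. The result is never worse
than the all-singletons or single-community baselines, which are checked
explicitly.

The resolution is selected on a grid (default `{0, 0.5, 1, 2, 4, 8, 16}` —
a handful of values is enough in practice) by maximizing the fraction of
nodes inside communities of the allowed 3–100 size range; ties resolve to
the smallest `r`. Oversize communities are subdivided by re-optimizing on
the induced subgraph, raising `r` if the subgraph refuses to split.

## Balanced regularized Markov clustering

The canonical flow matrix is the column-normalized adjacency with unit
self-loops. The iteration is `M ← Inflate_i(M_reg · M)` with entrywise
inflation and column renormalization, pruning entries below `1e-5` per
column (renormalizing afterwards; the column maximum always survives).
Clusters are the weakly connected components of the node → attractor map
(attractor = column argmax).

With balance `b > 0` the regularization matrix is recomputed each
iteration: entry (i, j) of the canonical flow is scaled by
`size(cluster(i))^(−b)` — i.e. the destination-node axis is weighted by the
current attractor-cluster size — and columns are renormalized. This
penalizes flow *into* large clusters; on hub-dominated graphs where plain
regularized MCL collapses cliques and spokes into one giant cluster, a
balance of ~1–1.5 separates the cliques. (A literal per-column scalar
rescale followed by column renormalization would be the identity, so the
destination-axis weighting is the only reading with the documented effect.)

Convergence is declared when the flow matrix is stationary (max entry
change < 1e-8) and the attractor assignment is unchanged over the last two
iterations; attractor stability alone triggers long before the flow has
settled and was observed to disagree with a fully converged reference run.
`max_iter = 200`; non-convergence returns the current clustering with a
flag. Preprocessing follows the original pipeline: sparsify, then scale
weights by the reciprocal of the minimum positive weight and round half-up
to integers (capped at 10⁶). Optional heavy-edge-matching coarsening
clusters a contracted graph and refines the projected solution with a short
MCL pass on the full graph; it is a runtime device, off by default at the
scales exercised here.

## Consensus

The standard consensus matrix counts, for each gene pair, the fraction of
input predictions co-clustering the pair; entries are exact multiples of
`1/n_methods` and genes left unclustered by a method count as not
co-clustered by it. The normalized variant divides each module's
contribution by its size and corrects for per-gene coverage; it is behind a
flag and not the default. The matrix is treated as a weighted network
(zero entries are non-edges; an optional threshold can sparsify small
entries) and re-clustered with the DSD pipeline, `k` set to the median
module count of the inputs (median rounded half to even — the tie policy
had to be fixed somewhere). Multi-network consensus is the entrywise mean
of per-network matrices over a shared gene ordering, with optional
zero-imputation for genes absent from a network.

## GWAS module scoring

Gene p-values over the declared background (all genes of the scored
network — using a larger background inflates module scores) are ranked
ascending with average ranks for ties, uniformized as
`u = (rank − 0.5)/N`, and mapped through the χ²₁ upper-quantile function so
the most significant gene receives the largest score. The rank transform
makes the test competitive (only the ordering matters — any rank-preserving
transformation of the input leaves module p-values unchanged) and keeps `u`
strictly inside (0, 1). Background genes missing from a score table
receive p = 1 before ranking by default (a "drop" policy is available). A
module of size m is scored by `T = Σ s_g` against the χ²ₘ upper tail.

BH correction is applied per (network, GWAS) over the submission's module
p-values, matching per-GWAS discovery. A module is trait-associated when
`q < FDR` for at least one GWAS; the challenge-style score counts each such
module once per network and sums over networks. The default cutoff is 5%
FDR.

Ranking robustness: with per-method tables of significant (module, GWAS)
pairs fixed from the full evaluation, GWAS subsets of size N are drawn
without replacement B times and each method re-scored by re-evaluating only
the "≥ 1 retained GWAS" union (re-running the full scoring inside each
subsample would change the question from GWAS-set sensitivity to
multiple-testing sensitivity). The paired Bayes factor of method m against
the top-scoring reference is #(reference beats m) / #(m beats or ties
reference); K < 3 is declared a tie. Identical methods give K = 0; a
method the reference always beats gives K = ∞.

## Comparison analytics

Prediction distance: module predictions are conceptually 0/1 vectors over
all gene pairs (1 = co-clustered); the distance is one minus their cosine,
computed by pair counting (`Σ C(|a∩b|, 2)` over module pairs) without
materializing O(N²) vectors. Empty predictions sit at distance 1 by
convention, with a warning.

Module overlap: Jaccard `J`, containment `S` (fraction of the first module
inside the second), and the inclusive upper-tail hypergeometric p of the
intersection, Bonferroni-adjusted by the number of pairs tested. The
category rules use the adjusted p (the correction is stated as applied, so
the thresholds are read against it): strong overlap (`J ≥ 0.5`, p < 0.05),
submodule (`J < 0.5`, `S − J ≥ 0.5`, p < 0.05), partial, insignificant —
mutually exclusive and exhaustive by construction. A module that is a
strong overlap of one partner and a submodule of another gets the combined
label. The trait-similarity network applies the same machinery to unions
of trait-associated module genes per network, drawing an edge when the
overlap is significant in at least `min_support` (default 3) of the
considered networks; node size and edge weight are the mean gene count and
mean Jaccard.

Functional enrichment uses the Wallenius non-central hypergeometric
distribution to account for annotation bias: the odds parameter is the
mean gene weight inside the annotation over the mean weight outside, so
uniform weights reduce exactly to the one-sided Fisher test (verified to
1e-9). Weights are user-supplied; a helper estimates them as each gene's
total annotation count normalized to mean 1. Bonferroni is applied over
the full modules × terms grid.

Representative annotations: binary module membership over the background is
regressed on the binary gene-by-gene-set matrix with an elastic net
(mixing 0.5; the ridge component lets duplicated gene sets share weight),
regularization strength chosen by 5-fold cross-validation with a fixed fold
seed. Gene sets with positive coefficients are reported in coefficient
order.

## Synthetic benchmarks

The planted-partition generator draws within-module edges with probability
`p_in` (weights uniform in `[0.5, 1.0]`) and between-module edges with
probability `p_out` (weights in `[0.05, 0.3]`) — strong, noisy blocks of
the kind module identification is expected to resolve. Gene-score tables
give genes of designated trait modules `p ~ Beta(a, 1)` with `a = 0.1`
(stochastically small, rank-preserving, single knob) and all other genes
uniform p-values; `a = 1` (no enrichment) is rejected. Random
modularizations partition a shuffled universe into fixed- or sampled-size
modules, leaving an undersized remainder unassigned. Every generator
derives an independent RNG stream from (seed, purpose) via a stable CRC so
streams never interfere and runs are reproducible across processes.

What these benchmarks do not emulate: the degree heterogeneity, weight
distributions and overlapping pathway structure of real molecular networks,
or the LD-induced correlation between gene-level GWAS p-values (inputs are
taken as independent gene scores; on real GWAS data, module p-values from
LD-aware gene fusion will differ somewhat). Passing the suite therefore
establishes correctness of the algorithms and calibration of the
statistics under the stated models, not field performance on any particular
real network.

## Problem sizes and runtime

The test suite and the acceptance script run planted benchmarks of 100–200
nodes, backgrounds of 5,000–20,000 genes, 2,000-module calibration sets and
t = 10⁴ walk-convergence checks; these sizes were chosen so every check
runs in seconds while leaving the conclusions (exactness, calibration,
recovery) unchanged at larger scale. The dense resolvent and flow-matrix
implementations are comfortable to a few thousand nodes; beyond that,
sparsification and the MCL coarsening path are the intended levers.
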