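# modulekit

Disease-relevant pathways rarely correspond to single genes: they appear as
*modules* — groups of genes more densely connected to each other than to the
rest of a molecular network. `modulekit` is a toolkit for finding such
modules in weighted gene/protein networks and for deciding, with GWAS data
as independent evidence, which of them are trait-associated. It is aimed at
computational biologists who have a network (protein–protein interaction,
signaling, co-expression, …) as an edge-list and gene-level GWAS p-values,
and want a reproducible path from "network" to "scored disease modules".

## What is inside

Three complementary module identification methods, an ensemble, and a
scoring/analysis layer:

- **DSD spectral clustering (`k1`).** The diffusion state distance between
  nodes *x* and *y* is the L1 distance between their expected random-walk
  visit-count vectors, with closed form
  `DSD(x, y) = ||(1_x − 1_y)(I − D⁻¹A + W)⁻¹||₁`, where `A` is the weighted
  adjacency, `D` the degree matrix and `W` the matrix whose rows are the
  degree-normalized stationary weights. The DSD matrix is converted to a
  similarity kernel `S = exp(−DSD²/2σ²)` and clustered with normalized
  spectral clustering with `k` cluster centers.
- **Resistance modularity (`m1`).** Weighted Newman–Girvan modularity `Q`
  maximized on the self-loop-augmented network `A + rI`. The resistance `r`
  tunes the resolution (larger `r` → smaller communities; `r = 0` is
  standard modularity) and is selected on a grid to maximize the fraction of
  nodes in communities of 3–100 genes.
- **Balanced regularized Markov clustering (`r1`).** Flow simulation with a
  canonical flow matrix re-entering at every expansion, inflation parameter
  `i`, and a balance parameter `b` that penalizes flow into large attractor
  clusters by `cluster_size^(−b)`.
- **Consensus.** A co-clustering fraction matrix `C` (`c_ij` = fraction of
  methods placing genes *i*, *j* in the same module) re-clustered with the
  DSD pipeline, `k` = median module count of the inputs; multi-network
  consensus averages per-network matrices.
- **GWAS module scoring.** Gene p-values over the network background are
  rank-transformed, mapped through the χ²₁ quantile, summed per module and
  tested against χ²ₘ — a competitive enrichment test. Modules significant
  at an FDR cutoff (Benjamini–Hochberg) for ≥ 1 GWAS are *trait-associated*;
  the challenge-style score counts each such module once. Ranking
  robustness is assessed by GWAS subsampling with paired Bayes factors
  (K < 3 ⇒ tie).
- **Analytics.** Prediction similarity (cosine distance over gene-pair
  co-clustering vectors), module-overlap categorization (Jaccard,
  containment, hypergeometric significance), trait-similarity networks,
  Wallenius-biased-urn functional enrichment, and representative-annotation
  selection via elastic net.
- **Synthetic benchmarks.** Planted-partition weighted networks with known
  truth, GWAS gene-score tables with Beta(a, 1)-enriched trait modules, and
  random modularizations as the null baseline.

All modules obey the validity rules used throughout: pairwise disjoint,
3–100 genes each.

## Worked example

Simulate a planted benchmark (4 modules × 25 genes, within-density 0.9,
between-density 0.02), cluster it, and score it against three simulated
GWASs in which modules 1–2 carry enriched gene p-values:

```sh
modulekit simulate network --sizes 25,25,25,25 --p-in 0.9 --p-out 0.02 \
    --seed 7 -o network.tsv
# -> network: 100 nodes, 1142 edges

modulekit cluster network.tsv --method k1 --k 4 --seed 7 -o modules_k1.tsv
# -> 4 modules written to modules_k1.tsv

modulekit score --modules modules_k1.tsv --gwas gwas1.tsv --gwas gwas2.tsv \
    --gwas gwas3.tsv --network network.tsv --fdr 0.05 -o scored.tsv
# -> score (trait-associated modules): 2
```

The four recovered modules coincide with the planted ones; exactly the two
modules whose genes carry enriched p-values are called trait-associated at
5% FDR, so the score is 2. `scored.tsv` holds the per-(module, GWAS) test
statistic `T`, nominal p and BH q-value, e.g. the first planted trait module
scores `T = 42.1`, `p = 0.017`, `q = 0.035` (significant) in the first GWAS,
while a null module sits at `p ≈ 1`.

The same pipeline is available as a library (`run_k1`, `run_m1`, `run_r1`,
`build_consensus`, `challenge_score`, …); see the docstrings and
`docs/methods.md`.

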