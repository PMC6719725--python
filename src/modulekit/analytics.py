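"""Cross-method and cross-network module comparison analytics.

Covers: a cosine distance between module predictions over gene-pair
co-clustering indicator vectors; Jaccard/containment overlap categorization
of module pairs with hypergeometric significance; a trait-similarity network
built from overlapping trait-module gene sets; functional enrichment with
the Wallenius non-central hypergeometric distribution (annotation-bias
aware, reducing to the one-sided Fisher test under uniform weights); and
representative-annotation selection by elastic-net regression of module
membership on a gene-by-gene-set matrix.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .netio import ModuleSet


# ---------------------------------------------------------------------------
# similarity of module predictions


def _pair_inner(ms1: ModuleSet, ms2: ModuleSet) -> float:
    """Inner product of the two gene-pair co-clustering indicator vectors,
    computed by pair counting: sum over module pairs of C(|a ∩ b|, 2)."""
    total = 0
    for a in ms1.modules:
        for b in ms2.modules:
            k = len(a & b)
            total += k * (k - 1) // 2
    return float(total)


def prediction_distance(ms1: ModuleSet, ms2: ModuleSet) -> float:
    """Cosine distance between module predictions.

    Conceptually each prediction is a 0/1 vector over all gene pairs of the
    shared universe (1 when the pair is co-clustered); the distance is one
    minus the cosine of those vectors, computed by pair counting without
    materializing the vectors. Empty predictions are at distance 1 by
    convention (with a warning).
    """
    norm1 = _pair_inner(ms1, ms1)
    norm2 = _pair_inner(ms2, ms2)
    if norm1 == 0 or norm2 == 0:
        warnings.warn("empty module prediction: distance 1 by convention")
        return 1.0
    return 1.0 - _pair_inner(ms1, ms2) / math.sqrt(norm1 * norm2)


def prediction_distance_matrix(predictions: list[ModuleSet]) -> np.ndarray:
    n = len(predictions)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = prediction_distance(predictions[i], predictions[j])
    return d


def mds_embedding(distance: np.ndarray, seed: int = 0) -> np.ndarray:
    """Optional 2-D multidimensional-scaling layout of a distance matrix
    (visualization helper only)."""
    from sklearn.manifold import MDS

    mds = MDS(n_components=2, dissimilarity="precomputed", random_state=seed,
              normalized_stress="auto")
    return mds.fit_transform(distance)


# ---------------------------------------------------------------------------
# overlap between trait-associated modules


@dataclass
class OverlapReport:
    jaccard: float
    containment: float  # fraction of A's genes inside B
    pvalue: float
    p_adj: float
    category: str


def overlap_pvalue(a: set, b: set, universe_size: int) -> float:
    """Upper-tail (inclusive) hypergeometric p of the observed overlap."""
    k = len(a & b)
    return float(stats.hypergeom.sf(k - 1, universe_size, len(b), len(a)))


def categorize_overlap(
    a: set, b: set, universe_size: int, n_tests: int = 1
) -> OverlapReport:
    """Classify the overlap of module A with module B.

    With Bonferroni-adjusted p (``p * n_tests`` capped at 1):
    strong overlap  J >= 0.5 and p < 0.05;
    submodule       J < 0.5, S - J >= 0.5 and p < 0.05 (A sits inside B);
    partial overlap J < 0.5, S - J < 0.5 and p < 0.05;
    insignificant   p >= 0.05.
    """
    if not a or not b:
        raise ValueError("empty module")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    inter = len(a & b)
    j = inter / len(a | b)
    s = inter / len(a)
    p = overlap_pvalue(a, b, universe_size)
    p_adj = min(1.0, p * n_tests)
    if p_adj >= 0.05:
        category = "insignificant"
    elif j >= 0.5:
        category = "strong_overlap"
    elif s - j >= 0.5:
        category = "submodule"
    else:
        category = "partial"
    return OverlapReport(jaccard=j, containment=s, pvalue=p, p_adj=p_adj,
                         category=category)


def combined_overlap_category(categories_with_partners: list[str]) -> str:
    """Summarize one module's overlap categories against all partners; a
    module that is a strong overlap of one partner and a submodule of
    another gets the combined label."""
    cats = set(categories_with_partners)
    if {"strong_overlap", "submodule"} <= cats:
        return "strong_and_submodule"
    for c in ("strong_overlap", "submodule", "partial"):
        if c in cats:
            return c
    return "insignificant"


# ---------------------------------------------------------------------------
# trait similarity network


@dataclass
class TraitNetwork:
    traits: list[str]
    node_size: dict[str, float]  # mean trait-module gene count across networks
    edges: dict[tuple[str, str], float]  # mean Jaccard across networks
    support: dict[tuple[str, str], int]  # networks with significant overlap


def trait_network(
    trait_genes: dict[str, dict[str, set[str]]],
    universe_sizes: dict[str, int],
    min_support: int = 3,
    alpha: float = 0.05,
) -> TraitNetwork:
    """Build the trait-trait similarity network.

    ``trait_genes[network][trait]`` is the union of module genes associated
    with the trait in that network; ``universe_sizes`` gives each network's
    gene count for the hypergeometric test. An edge joins two traits when
    their gene-set overlap is Bonferroni-significant in at least
    ``min_support`` networks; edge weight is the mean Jaccard and node size
    the mean trait gene count across the considered networks. Traits with
    empty gene sets everywhere are excluded.
    """
    networks = sorted(trait_genes)
    all_traits = sorted({t for n in networks for t in trait_genes[n]})
    traits = [
        t
        for t in all_traits
        if any(trait_genes[n].get(t) for n in networks)
    ]
    pairs = [(a, b) for i, a in enumerate(traits) for b in traits[i + 1 :]]
    n_tests = max(1, len(pairs) * len(networks))
    edges, support = {}, {}
    for a, b in pairs:
        sig = 0
        jaccards = []
        for net in networks:
            ga = trait_genes[net].get(a) or set()
            gb = trait_genes[net].get(b) or set()
            if not ga or not gb:
                continue
            inter = len(ga & gb)
            jaccards.append(inter / len(ga | gb))
            p = overlap_pvalue(ga, gb, universe_sizes[net])
            if min(1.0, p * n_tests) < alpha:
                sig += 1
        if sig >= min_support and jaccards:
            edges[(a, b)] = float(np.mean(jaccards))
            support[(a, b)] = sig
    node_size = {
        t: float(
            np.mean([len(trait_genes[n].get(t) or set()) for n in networks])
        )
        for t in traits
    }
    return TraitNetwork(traits=traits, node_size=node_size, edges=edges,
                        support=support)


# ---------------------------------------------------------------------------
# functional enrichment


def enrichment_test(
    module: set,
    annotation: set,
    background: set,
    weights: dict[str, float] | None = None,
) -> float:
    """Enrichment p of a module in an annotation gene set.

    Uses the Wallenius non-central hypergeometric distribution with odds
    equal to the mean gene weight inside the annotation divided by the mean
    weight outside (within the background), accounting for annotation bias;
    uniform weights reduce exactly to the one-sided Fisher (central
    hypergeometric) test. Upper tail, inclusive of the observed count.
    """
    background = set(background)
    module = set(module) & background
    annot = set(annotation) & background
    if not annot:
        warnings.warn("annotation does not intersect the background; p = 1")
        return 1.0
    if not module:
        raise ValueError("module does not intersect the background")
    if weights:
        w = {g: float(weights.get(g, 1.0)) for g in background}
        if any(x <= 0 for x in w.values()):
            raise ValueError("weights must be positive")
        inside = np.mean([w[g] for g in annot])
        outside_genes = background - annot
        outside = np.mean([w[g] for g in outside_genes]) if outside_genes else 1.0
        odds = inside / outside
    else:
        odds = 1.0
    k = len(module & annot)
    n_bg, n_annot, n_mod = len(background), len(annot), len(module)
    if odds == 1.0:
        return float(stats.hypergeom.sf(k - 1, n_bg, n_annot, n_mod))
    return float(stats.nchypergeom_wallenius.sf(k - 1, n_bg, n_annot, n_mod, odds))


def annotation_bias_weights(collection: dict[str, set[str]], background: set
                            ) -> dict[str, float]:
    """Per-gene weights estimated as each gene's total annotation count,
    normalized to mean 1 over the background (the annotation-bias covariate
    used by bias-aware enrichment)."""
    counts = {g: 0 for g in background}
    for genes in collection.values():
        for g in genes:
            if g in counts:
                counts[g] += 1
    vals = np.array([counts[g] + 1.0 for g in sorted(background)])  # +1: keep positive
    mean = vals.mean()
    return {g: (counts[g] + 1.0) / mean for g in background}


def enrich_collection(
    modules: ModuleSet,
    collection: dict[str, set[str]],
    background: set,
    weights: dict[str, float] | None = None,
):
    """Test every (module, annotation term) pair; Bonferroni over the full
    M x T grid. Returns a list of dicts sorted by adjusted p."""
    n_tests = max(1, len(modules.modules) * len(collection))
    rows = []
    for i, module in enumerate(modules.modules):
        for term, genes in collection.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = enrichment_test(module, genes, background, weights)
            rows.append(
                {"module_id": i, "term": term, "pvalue": p,
                 "p_adj": min(1.0, p * n_tests)}
            )
    return sorted(rows, key=lambda r: r["p_adj"])


# ---------------------------------------------------------------------------
# representative annotation selection


def select_annotations(
    module: set,
    collection: dict[str, set[str]],
    background: set | None = None,
    l1_ratio: float = 0.5,
    seed: int = 0,
) -> list[tuple[str, float]]:
    """Select few, informative annotations for a module by elastic net.

    Membership of each background gene in the module (binary y) is regressed
    on the binary gene-by-gene-set matrix G with elastic-net mixing 0.5 and
    the regularization strength chosen by 5-fold cross-validation; gene sets
    with positive coefficients are returned, ordered by coefficient size.
    """
    if not collection:
        raise ValueError("empty annotation collection")
    terms = sorted(collection)
    if background is None:
        background = set().union(*(collection[t] for t in terms))
    genes = sorted(background)
    if not set(module) & set(genes):
        return []
    g_matrix = np.zeros((len(genes), len(terms)))
    for j, t in enumerate(terms):
        members = collection[t]
        for i, g in enumerate(genes):
            if g in members:
                g_matrix[i, j] = 1.0
    y = np.array([1.0 if g in module else 0.0 for g in genes])
    if y.std() == 0:
        return []
    from sklearn.linear_model import ElasticNetCV
    from sklearn.model_selection import KFold

    cv = KFold(n_splits=5, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ElasticNetCV(l1_ratio=l1_ratio, cv=cv, random_state=seed,
                             max_iter=5000)
        model.fit(g_matrix, y)
    selected = [
        (terms[j], float(c)) for j, c in enumerate(model.coef_) if c > 0
    ]
    return sorted(selected, key=lambda tc: (-tc[1], tc[0]))
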