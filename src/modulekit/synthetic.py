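"""Synthetic benchmarks: planted-module networks, GWAS gene scores and
random modularizations.

These generators emulate the statistical structure the toolkit's pipelines
assume: a planted-partition weighted network with tunable within/between
edge densities stands in for the challenge networks; per-GWAS gene-score
tables give genes of designated *trait modules* enriched (stochastically
small, Beta(a, 1)-distributed) p-values while all other genes are uniform;
and random disjoint modularizations of a gene universe provide the null
baseline against which challenge scores are calibrated.

All generators are deterministic under a fixed seed; each derives an
independent RNG stream from (seed, purpose) so adding draws to one generator
never perturbs another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .netio import ModuleSet, Network


def _rng(seed: int, purpose: str) -> np.random.Generator:
    # crc32 of the purpose string: process-independent stream separation
    return np.random.default_rng([seed, zlib.crc32(purpose.encode())])


@dataclass
class PlantedBenchmark:
    network: Network
    truth: ModuleSet
    trait_modules: list[int] = field(default_factory=list)
    params: dict = field(default_factory=dict)


def planted_partition(
    sizes: list[int],
    p_in: float,
    p_out: float,
    w_in: tuple[float, float] = (0.5, 1.0),
    w_out: tuple[float, float] = (0.05, 0.3),
    seed: int = 0,
) -> PlantedBenchmark:
    """Weighted planted-partition network with known ground-truth modules.

    Within-module node pairs get an edge with probability ``p_in`` and a
    weight uniform in ``w_in``; between-module pairs with probability
    ``p_out`` and weight uniform in ``w_out``. Node labels are ``g0001``...
    in module order, so truth module i covers a contiguous block.
    """
    if any(s < 3 for s in sizes):
        raise ValueError("module sizes must be >= 3")
    if not (0 <= p_out < p_in <= 1):
        raise ValueError("need p_in > p_out (and both in [0, 1])")
    rng = _rng(seed, "planted_partition")
    n = sum(sizes)
    width = max(4, len(str(n)))
    labels = [f"g{i + 1:0{width}d}" for i in range(n)]
    bounds = np.cumsum([0] + list(sizes))
    member = np.zeros(n, dtype=int)
    for m, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        member[lo:hi] = m
    triples = []
    for i in range(n):
        for j in range(i + 1, n):
            same = member[i] == member[j]
            p = p_in if same else p_out
            if rng.random() < p:
                lo, hi = w_in if same else w_out
                triples.append((labels[i], labels[j], rng.uniform(lo, hi)))
    net = Network.from_edges(triples, directed=False, extra_nodes=labels)
    truth = ModuleSet(
        modules=[
            frozenset(labels[lo:hi]) for lo, hi in zip(bounds[:-1], bounds[1:])
        ],
        method_id="truth",
    )
    return PlantedBenchmark(
        network=net,
        truth=truth,
        params={"sizes": list(sizes), "p_in": p_in, "p_out": p_out,
                "w_in": w_in, "w_out": w_out, "seed": seed},
    )


def simulate_gene_scores(
    benchmark: PlantedBenchmark,
    trait_module_ids: list[int],
    beta_a: float = 0.1,
    n_gwas: int = 1,
    seed: int = 0,
    background: set[str] | None = None,
):
    """Simulate per-GWAS gene-level p-value tables.

    Genes of the designated trait modules draw ``p ~ Beta(beta_a, 1)`` with
    ``beta_a < 1`` (stochastically small under enrichment, exactly uniform
    at the rejected boundary ``beta_a = 1``); all other background genes
    draw uniform p-values. GWASs are independent draws.
    """
    from .scoring import GeneScoreTable

    if not (0 < beta_a < 1):
        raise ValueError("beta_a must lie in (0, 1): beta_a = 1 is no enrichment")
    truth = benchmark.truth.modules
    for mid in trait_module_ids:
        if not (0 <= mid < len(truth)):
            raise ValueError(f"trait module id {mid} outside truth modules")
    trait_genes = set().union(*(truth[m] for m in trait_module_ids)) if trait_module_ids else set()
    bg = sorted(background if background is not None else benchmark.network.nodes)
    rng = _rng(seed, "simulate_gene_scores")
    tables = []
    for g_idx in range(n_gwas):
        scores = {}
        for g in bg:
            if g in trait_genes:
                p = float(rng.beta(beta_a, 1.0))
            else:
                p = float(rng.uniform())
            scores[g] = min(max(p, 1e-300), 1.0)
        tables.append(
            GeneScoreTable(gwas_id=f"gwas{g_idx + 1}", scores=scores,
                           background=set(bg))
        )
    benchmark.trait_modules = list(trait_module_ids)
    return tables


def random_modules(
    universe: set[str],
    size_sampler=10,
    seed: int = 0,
    min_size: int = 3,
    max_size: int = 100,
) -> ModuleSet:
    """Random disjoint modularization of (a subset of) a gene universe.

    ``size_sampler`` is either a fixed module size or a callable
    ``rng -> int`` drawing sizes in ``[min_size, max_size]``. Genes are
    consumed in shuffled order; a remainder smaller than ``min_size`` is
    left module-free (modules need not cover all genes).
    """
    rng = _rng(seed, "random_modules")
    genes = sorted(str(g) for g in universe)
    if len(genes) < min_size:
        raise ValueError("universe too small for a single module")
    rng.shuffle(genes)
    modules = []
    pos = 0
    while pos < len(genes):
        size = size_sampler(rng) if callable(size_sampler) else int(size_sampler)
        if not (min_size <= size <= max_size):
            raise ValueError(f"sampled module size {size} outside "
                             f"[{min_size}, {max_size}]")
        if len(genes) - pos < size:
            break
        modules.append(frozenset(genes[pos:pos + size]))
        pos += size
    return ModuleSet(modules=modules, method_id="random")
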