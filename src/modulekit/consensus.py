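"""Consensus module predictions from an ensemble of clusterings.

The co-clustering fraction matrix ``C`` has entries ``c_ij`` equal to the
fraction of methods that put genes i and j in the same module; it is treated
as a weighted adjacency matrix of a functional gene network and re-clustered
with the top challenge method (the DSD spectral pipeline), with the number
of cluster centers set to the median module count of the contributing
methods. Multi-network consensus averages the per-network matrices
entrywise.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .dsd import K1Params, run_k1
from .netio import ModuleSet, Network


@dataclass
class ConsensusMatrix:
    genes: list[str]
    values: sp.csr_matrix  # symmetric, zero diagonal stored implicitly as 1
    n_methods: int

    def toarray(self) -> np.ndarray:
        dense = self.values.toarray()
        np.fill_diagonal(dense, 1.0)
        return dense


def build_consensus(
    predictions: list[ModuleSet],
    universe: set[str],
    normalized: bool = False,
) -> ConsensusMatrix:
    """Build the consensus matrix from a list of module predictions.

    Standard construction: ``c_ij = (# methods co-clustering i and j) / n``.
    Genes a method leaves outside any module are simply never co-clustered by
    it. The normalized variant divides each module's contribution by its
    size and each gene pair's total by the number of methods that assigned
    both genes to some module (background-gene correction); entries are then
    no longer exact multiples of 1/n.
    """
    if not predictions:
        raise ValueError("need at least one prediction")
    if not universe:
        raise ValueError("empty gene universe")
    genes = sorted(str(g) for g in universe)
    idx = {g: i for i, g in enumerate(genes)}
    for ms in predictions:
        stray = ms.genes() - set(genes)
        if stray:
            raise ValueError(f"module genes outside universe: {sorted(stray)[:5]}")
    n = len(genes)
    acc = sp.lil_matrix((n, n))
    coverage = np.zeros(n)
    for ms in predictions:
        for module in ms.modules:
            members = sorted(idx[g] for g in module)
            w = 1.0 / len(members) if normalized else 1.0
            for a_pos, a in enumerate(members):
                for b in members[a_pos + 1 :]:
                    acc[a, b] += w
                    acc[b, a] += w
        for g in ms.genes():
            coverage[idx[g]] += 1
    acc = acc.tocsr()
    if normalized:
        cov = np.minimum.outer(coverage, coverage)
        cov[cov == 0] = 1.0
        dense = acc.toarray() / cov
        acc = sp.csr_matrix(dense)
    else:
        acc = acc / len(predictions)
    return ConsensusMatrix(genes=genes, values=acc, n_methods=len(predictions))


def median_module_count(predictions: list[ModuleSet]) -> int:
    """Median number of modules per prediction, rounded half to even."""
    counts = [len(ms.modules) for ms in predictions]
    med = statistics.median(counts)
    return max(1, round(med))


def consensus_to_network(c: ConsensusMatrix, threshold: float = 0.0) -> Network:
    """Interpret C as a weighted network; entries <= threshold become
    non-edges (zeros are always absent)."""
    coo = sp.triu(c.values, k=1).tocoo()
    triples = [
        (c.genes[i], c.genes[j], v)
        for i, j, v in zip(coo.row, coo.col, coo.data)
        if v > threshold
    ]
    if not triples:
        raise ValueError("consensus matrix has no positive off-diagonal entries")
    return Network.from_edges(triples, directed=False, extra_nodes=c.genes)


def cluster_consensus(
    c: ConsensusMatrix,
    predictions: list[ModuleSet] | None = None,
    k: int | None = None,
    params: K1Params | None = None,
    threshold: float = 0.0,
) -> ModuleSet:
    """Re-cluster a consensus matrix with the DSD spectral pipeline.

    ``k`` defaults to the median module count of the contributing
    predictions (the only free parameter of the K1 method).
    """
    if k is None:
        if predictions is None:
            raise ValueError("give either k or the contributing predictions")
        k = median_module_count(predictions)
    params = params or K1Params()
    params = K1Params(
        k=k,
        sigma=params.sigma,
        min_size=params.min_size,
        max_size=params.max_size,
        seed=params.seed,
    )
    net = consensus_to_network(c, threshold)
    ms = run_k1(net, params)
    ms.method_id = "consensus"
    return ms


def multinet_consensus(
    per_network: list[ConsensusMatrix], impute_missing: bool = False
) -> ConsensusMatrix:
    """Entrywise mean of network-specific consensus matrices.

    All matrices must share the gene ordering; with ``impute_missing`` the
    union universe is used and genes absent from a network contribute zero
    rows/columns for that network.
    """
    if not per_network:
        raise ValueError("need at least one consensus matrix")
    universes = [tuple(c.genes) for c in per_network]
    if len(set(universes)) > 1:
        if not impute_missing:
            raise ValueError(
                "consensus matrices have different gene universes; "
                "set impute_missing=True to align on the union"
            )
        union = sorted(set().union(*(set(u) for u in universes)))
        idx = {g: i for i, g in enumerate(union)}
        acc = np.zeros((len(union), len(union)))
        for c in per_network:
            rows = np.array([idx[g] for g in c.genes])
            acc[np.ix_(rows, rows)] += c.values.toarray()
        mean = sp.csr_matrix(acc / len(per_network))
        genes = union
    else:
        mean = sum(c.values for c in per_network) / len(per_network)
        genes = per_network[0].genes
    return ConsensusMatrix(
        genes=list(genes),
        values=sp.csr_matrix(mean),
        n_methods=sum(c.n_methods for c in per_network),
    )
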