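"""Balanced regularized Markov clustering (method R1).

Markov clustering (MCL) simulates flow on the graph: a column-stochastic
flow matrix is alternately *expanded* (matrix product) and *inflated*
(entrywise power, then column renormalization), which concentrates flow on
attractor nodes; clusters are read off the attractor structure. The
regularized variant (R-MCL) replaces self-expansion by multiplication with a
fixed *canonical flow matrix* so the original topology keeps influencing the
process after the first iteration, and the balanced variant recomputes the
regularization matrix each iteration with a penalty on large attractor
clusters, tunable through the balance parameter ``b`` (``b = 0`` is plain
R-MCL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import Network, ModuleSet, sparsify


@dataclass
class MclParams:
    inflation: float = 2.0
    balance: float = 0.0
    coarsen: bool = False
    coarsen_size: int = 500
    prune_threshold: float = 1e-5
    max_iter: int = 200
    min_size: int = 3
    max_size: int = 100
    self_loop: float = 1.0
    sparsify_min_weight: float | None = None
    sparsify_quantile: float | None = None
    integerize: bool = True

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must be > 1")
        if self.balance < 0:
            raise ValueError("balance must be >= 0")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


def canonical_flow(
    net: Network, order: list[str] | None = None, self_loop: float = 1.0
) -> np.ndarray:
    """Column-stochastic flow matrix of the self-loop-augmented network.

    Entry (i, j) is the probability of a step from node j to node i,
    proportional to edge weight; every node gets a self-loop (standard MCL
    convention) so isolated nodes yield a unit self-loop column.
    """
    order = net.node_list() if order is None else order
    a = net.adjacency(order) + self_loop * np.eye(len(order))
    return a / a.sum(axis=0, keepdims=True)


def _attractor_partition(m: np.ndarray) -> np.ndarray:
    """Assign each node (column) to its attractor (row argmax), then merge
    assignments into clusters via the weakly connected attractor structure."""
    n = m.shape[0]
    attractor = np.argmax(m, axis=0)
    # union-find over node -> attractor links
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        ra, rb = find(j), find(int(attractor[j]))
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(j) for j in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def _inflate_prune(m: np.ndarray, inflation: float, threshold: float) -> np.ndarray:
    m = np.power(m, inflation)
    m /= m.sum(axis=0, keepdims=True)
    if threshold > 0:
        m[m < threshold] = 0.0
        col = m.sum(axis=0, keepdims=True)
        # pruning can never empty a column (the max entry survives)
        m /= col
    return m


def bmlrmcl(
    net: Network,
    params: MclParams | None = None,
    order: list[str] | None = None,
    init: np.ndarray | None = None,
    n_iter: int | None = None,
) -> tuple[list[set[str]], bool]:
    """Run balanced regularized MCL; returns (clusters, converged flag).

    Iterates ``M <- Inflate_i(M_reg @ M)`` with pruning, where ``M_reg`` is
    the canonical flow matrix, rescaled each iteration (for ``b > 0``) by
    ``size(cluster(i))^(-b)`` on the destination-node axis and
    column-renormalized, penalizing flow into large attractor clusters.
    Convergence: the flow matrix is stationary (max entry change < 1e-8)
    and the attractor cluster assignment is unchanged across the final two
    iterations — attractor stability alone can trigger long before the flow
    has settled.
    """
    params = params or MclParams()
    order = net.node_list() if order is None else order
    mg = canonical_flow(net, order, params.self_loop)
    m = mg.copy() if init is None else init
    labels = _attractor_partition(m)
    converged = False
    max_iter = params.max_iter if n_iter is None else n_iter
    for _ in range(max_iter):
        if params.balance > 0:
            sizes = np.bincount(labels)
            row_w = sizes[labels] ** (-params.balance)
            m_reg = mg * row_w[:, None]
            m_reg /= m_reg.sum(axis=0, keepdims=True)
        else:
            m_reg = mg
        m_new = _inflate_prune(m_reg @ m, params.inflation, params.prune_threshold)
        new_labels = _attractor_partition(m_new)
        delta = float(np.max(np.abs(m_new - m)))
        m = m_new
        if delta < 1e-8 and np.array_equal(new_labels, labels):
            labels = new_labels
            converged = True
            break
        labels = new_labels
    clusters = [
        {order[i] for i in np.flatnonzero(labels == c)} for c in np.unique(labels)
    ]
    return clusters, converged


def integerize_weights(net: Network, cap: float = 1e6) -> Network:
    """Rescale weights by 1 / min positive weight and round half-up to
    integers (capped), as the original pipeline required integer weights."""
    if not net.edges:
        return net
    scale = 1.0 / net.min_weight()
    edges = {}
    for e, w in net.edges.items():
        edges[e] = float(min(np.floor(w * scale + 0.5), cap))
    out = Network(edges=edges, directed=net.directed)
    out.nodes.update(net.nodes)
    return out


def heavy_edge_coarsen(net: Network, target_size: int):
    """Single-scheme heavy-edge matching coarsening down to >= target_size.

    Greedily matches each unmatched node with its heaviest unmatched
    neighbor and contracts the pair; repeats until the graph has at most
    ``target_size`` nodes or no contraction is possible. Returns the coarse
    network and the mapping coarse-node -> set of original nodes.
    """
    groups = {n: {n} for n in net.nodes}
    current = net
    while current.n_nodes > target_size:
        matched: set[str] = set()
        merges: list[tuple[str, str]] = []
        nbr_w: dict[str, list[tuple[float, str]]] = {n: [] for n in current.nodes}
        for (u, v), w in current.edges.items():
            nbr_w[u].append((w, v))
            nbr_w[v].append((w, u))
        for n in current.node_list():
            if n in matched or not nbr_w[n]:
                continue
            cands = [(w, v) for w, v in nbr_w[n] if v not in matched]
            if not cands:
                continue
            _, mate = max(cands, key=lambda t: (t[0], t[1]))
            merges.append((n, mate))
            matched.update((n, mate))
        if not merges:
            break
        rename = {}
        for a, b in merges:
            keep = min(a, b)
            drop = max(a, b)
            rename[drop] = keep
            groups[keep] = groups[keep] | groups[drop]
            del groups[drop]
        triples = []
        for (u, v), w in current.edges.items():
            u2, v2 = rename.get(u, u), rename.get(v, v)
            if u2 != v2:
                triples.append((u2, v2, w))
        # sum parallel weights during contraction
        agg: dict[tuple[str, str], float] = {}
        for u2, v2, w in triples:
            key = (min(u2, v2), max(u2, v2))
            agg[key] = agg.get(key, 0.0) + w
        current = Network.from_edges(
            ((u, v, w) for (u, v), w in agg.items()),
            directed=False,
            extra_nodes=set(groups),
        )
    return current, groups


def _recluster_oversize(net: Network, cluster: set[str], params: MclParams, depth=0):
    if len(cluster) <= params.max_size:
        return [cluster]
    sub = net.subgraph(cluster)
    infl = params.inflation + 0.4 * depth  # sharpen if a level refuses to split
    sub_params = MclParams(
        inflation=infl,
        balance=max(params.balance, 1.0),
        prune_threshold=params.prune_threshold,
        max_iter=params.max_iter,
        min_size=params.min_size,
        max_size=params.max_size,
        self_loop=params.self_loop,
    )
    parts, _ = bmlrmcl(sub, sub_params)
    if len(parts) == 1 or depth > 10:
        ordered = sorted(cluster)
        half = len(ordered) // 2
        parts = [set(ordered[:half]), set(ordered[half:])]
    out = []
    for p in parts:
        out.extend(_recluster_oversize(net, p, params, depth + 1))
    return out


def run_r1(net: Network, params: MclParams | None = None) -> ModuleSet:
    """Full R1 pipeline: sparsify, integerize, (optionally) coarsen, run
    balanced regularized MCL, recursively recluster oversize clusters and
    drop undersize ones."""
    params = params or MclParams()
    work = net
    if params.sparsify_min_weight is not None or params.sparsify_quantile is not None:
        work = sparsify(
            work,
            min_weight=params.sparsify_min_weight,
            keep_quantile=params.sparsify_quantile,
        )
    if params.integerize and work.edges:
        work = integerize_weights(work)
    if params.coarsen and work.n_nodes > params.coarsen_size:
        coarse, groups = heavy_edge_coarsen(work, params.coarsen_size)
        coarse_clusters, _ = bmlrmcl(coarse, params)
        # project to the full graph and run one refinement MCL pass
        order = work.node_list()
        idx = {g: i for i, g in enumerate(order)}
        proj = np.zeros((len(order), len(order)))
        for cl in coarse_clusters:
            members = sorted(set().union(*(groups[c] for c in cl)))
            rows = [idx[g] for g in members]
            for j in rows:
                proj[rows, j] = 1.0 / len(rows)
        clusters, _ = bmlrmcl(work, params, order=order, init=proj, n_iter=2)
    else:
        clusters, _ = bmlrmcl(work, params)
    modules: list[frozenset[str]] = []
    for cl in clusters:
        for piece in _recluster_oversize(work, cl, params):
            if len(piece) >= params.min_size:
                modules.append(frozenset(piece))
    ms = ModuleSet(modules=modules, method_id="R1")
    ms.validate(params.min_size, params.max_size, universe=net.nodes)
    return ms
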