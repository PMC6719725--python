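"""Network and module-set containers, file formats and shared preprocessing.

The on-disk formats are the ones used by the module identification challenge
ecosystem: 3-column edge-list TSV for networks (``gene1  gene2  weight``),
one-module-per-line TSV for module sets (``module_id  score  gene1  gene2 ...``),
2-column ``gene  pvalue`` tables for gene-level GWAS scores, and standard GMT
for annotation gene-set collections.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import numpy as np


class NetworkFormatError(ValueError):
    """Malformed network/module file (carries the offending line number)."""


@dataclass
class Network:
    """A weighted gene/protein network.

    Edges are stored once, keyed by node pair. For undirected networks the
    pair is order-normalized (``u < v``); duplicate records of the same pair
    keep the maximum weight (weights are confidence scores, so the strongest
    evidence wins). Self-loops are rejected on input; they are only ever
    introduced internally (e.g. by the resistance augmentation of the
    modularity method).
    """

    edges: dict[tuple[str, str], float]
    directed: bool = False
    #: nodes may include isolated genes with no surviving edge
    nodes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for (u, v), w in self.edges.items():
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed in input")
            if not w > 0:
                raise ValueError(f"non-positive weight {w} on edge ({u}, {v})")
            self.nodes.add(u)
            self.nodes.add(v)

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edge_iter,
        directed: bool = False,
        extra_nodes=(),
    ) -> "Network":
        """Build a network from ``(u, v, w)`` triples with deduplication."""
        edges: dict[tuple[str, str], float] = {}
        for u, v, w in edge_iter:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} not allowed in input")
            w = float(w)
            if not w > 0:
                raise ValueError(f"non-positive weight {w} on edge ({u}, {v})")
            key = (u, v) if directed else (min(u, v), max(u, v))
            if key in edges:
                edges[key] = max(edges[key], w)
            else:
                edges[key] = w
        net = cls(edges=edges, directed=directed)
        net.nodes.update(str(n) for n in extra_nodes)
        return net

    # -- basic queries -----------------------------------------------------

    def node_list(self) -> list[str]:
        """Canonical (sorted) node order used by all matrix-based methods."""
        return sorted(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def min_weight(self) -> float:
        if not self.edges:
            raise ValueError("network has no edges")
        return min(self.edges.values())

    def adjacency(self, order: list[str] | None = None) -> np.ndarray:
        """Dense adjacency matrix in the given (default canonical) order."""
        order = self.node_list() if order is None else order
        idx = {g: i for i, g in enumerate(order)}
        a = np.zeros((len(order), len(order)))
        for (u, v), w in self.edges.items():
            if u in idx and v in idx:
                a[idx[u], idx[v]] = w
                if not self.directed:
                    a[idx[v], idx[u]] = w
        return a

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from((u, v, w) for (u, v), w in self.edges.items())
        return g

    def subgraph(self, keep: set[str]) -> "Network":
        edges = {
            (u, v): w for (u, v), w in self.edges.items() if u in keep and v in keep
        }
        net = Network(edges=edges, directed=self.directed)
        net.nodes.update(n for n in self.nodes if n in keep)
        return net

    def connected_components(self) -> list[set[str]]:
        import networkx as nx

        g = self.to_networkx()
        if self.directed:
            comps = nx.weakly_connected_components(g)
        else:
            comps = nx.connected_components(g)
        return sorted((set(c) for c in comps), key=lambda c: (-len(c), min(c)))


@dataclass
class ModuleSet:
    """A collection of disjoint gene modules (one challenge submission).

    Challenge validity rules: modules are pairwise disjoint and, after
    finalization, each comprises between ``min_size`` and ``max_size`` genes
    (3 and 100 by default). Modules need not cover every network gene.
    """

    modules: list[frozenset[str]]
    network_id: str = ""
    method_id: str = ""

    def __post_init__(self) -> None:
        self.modules = [frozenset(m) for m in self.modules]

    def genes(self) -> set[str]:
        out: set[str] = set()
        for m in self.modules:
            out |= m
        return out

    def sizes(self) -> list[int]:
        return [len(m) for m in self.modules]

    def membership(self) -> dict[str, int]:
        """gene -> module index; raises if modules overlap."""
        memb: dict[str, int] = {}
        for i, m in enumerate(self.modules):
            for g in m:
                if g in memb:
                    raise ValueError(f"gene {g!r} appears in more than one module")
                memb[g] = i
        return memb

    def validate(
        self,
        min_size: int = 3,
        max_size: int = 100,
        universe: set[str] | None = None,
    ) -> None:
        self.membership()  # disjointness
        for i, m in enumerate(self.modules):
            if not (min_size <= len(m) <= max_size):
                raise ValueError(
                    f"module {i} has size {len(m)}, outside [{min_size}, {max_size}]"
                )
        if universe is not None:
            stray = self.genes() - set(universe)
            if stray:
                raise ValueError(f"module genes outside universe: {sorted(stray)[:5]}")

    def finalize(self, min_size: int = 3, max_size: int = 100) -> "ModuleSet":
        """Drop undersize modules; oversize modules must be handled upstream."""
        kept = [m for m in self.modules if len(m) >= min_size]
        for m in kept:
            if len(m) > max_size:
                raise ValueError("oversize module reached finalize; split it first")
        return replace(self, modules=kept)


# ---------------------------------------------------------------------------
# readers / writers


def read_network(path, directed: bool = False, header: bool = False) -> Network:
    """Read a 3-column edge-list TSV (``gene1 gene2 weight``).

    Undirected duplicate records (``u v`` vs ``v u``) are collapsed keeping
    the maximum weight. Malformed lines raise :class:`NetworkFormatError`
    with the 1-based line number.
    """
    triples = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) == 1:
                parts = line.split()
            if len(parts) != 3:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            u, v, w = parts
            try:
                w = float(w)
            except ValueError as exc:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: weight {parts[2]!r} is not a number"
                ) from exc
            if not w > 0:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: weight must be positive, got {w}"
                )
            triples.append((u, v, w))
    return Network.from_edges(triples, directed=directed)


def write_network(net: Network, path, header: bool = False) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("gene1\tgene2\tweight\n")
        for (u, v), w in sorted(net.edges.items()):
            fh.write(f"{u}\t{v}\t{w:.10g}\n")


def read_modules(path, strict: bool = False, **labels) -> ModuleSet:
    """Read the one-module-per-line dialect: ``id TAB score TAB gene...``."""
    modules = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: expected id, score and >=1 gene"
                )
            modules.append(frozenset(parts[2:]))
    ms = ModuleSet(modules=modules, **labels)
    if strict:
        ms.membership()
    return ms


def write_modules(ms: ModuleSet, path) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(ms.modules, start=1):
            genes = "\t".join(sorted(m))
            fh.write(f"{i}\t1.0\t{genes}\n")


def read_gene_scores(path) -> dict[str, float]:
    """Read a ``gene TAB pvalue`` table (header required)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if not {"gene", "pvalue"} <= set(df.columns):
        raise NetworkFormatError(f"{path}: expected header 'gene\\tpvalue'")
    if df["gene"].duplicated().any():
        dup = df["gene"][df["gene"].duplicated()].iloc[0]
        raise NetworkFormatError(f"{path}: duplicate gene {dup!r}")
    return dict(zip(df["gene"].astype(str), df["pvalue"].astype(float)))


def write_gene_scores(scores: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tpvalue\n")
        for g in sorted(scores):
            fh.write(f"{g}\t{scores[g]:.10g}\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file: ``set_name TAB description TAB gene...`` per line."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"{path}: line {lineno}: GMT needs name, description, genes"
                )
            sets[parts[0]] = set(parts[2:])
    return sets


# ---------------------------------------------------------------------------
# preprocessing shared by the clustering methods


def sparsify(
    net: Network,
    min_weight: float | None = None,
    keep_quantile: float | None = None,
) -> Network:
    """Discard weak edges below a threshold; isolated nodes are retained.

    Exactly one of ``min_weight`` / ``keep_quantile`` must be given. With
    ``keep_quantile=q`` the strongest fraction ``q`` of edges survives; ties
    at the threshold weight are all kept (deterministic, order-independent).
    """
    if (min_weight is None) == (keep_quantile is None):
        raise ValueError("give exactly one of min_weight / keep_quantile")
    if keep_quantile is not None:
        if not (0 < keep_quantile <= 1):
            raise ValueError("keep_quantile must be in (0, 1]")
        weights = sorted(net.edges.values(), reverse=True)
        n_keep = max(1, int(np.ceil(keep_quantile * len(weights))))
        threshold = weights[min(n_keep, len(weights)) - 1]
    else:
        threshold = min_weight
    edges = {e: w for e, w in net.edges.items() if w >= threshold}
    out = Network(edges=edges, directed=net.directed)
    out.nodes.update(net.nodes)
    return out


def make_strongly_connected(net: Network) -> Network:
    """Add low-weight back edges to a directed network.

    For every directed edge u->v without a reciprocal v->u, a back edge v->u
    is added with weight equal to 1/100 of the lowest edge weight in the
    network, so that a weakly connected input becomes strongly connected
    (the random-walk methods require irreducibility).
    """
    if not net.directed:
        raise ValueError("make_strongly_connected applies to directed networks only")
    back_w = net.min_weight() / 100.0
    edges = dict(net.edges)
    for (u, v) in net.edges:
        if (v, u) not in edges:
            edges[(v, u)] = back_w
    out = Network(edges=edges, directed=True)
    out.nodes.update(net.nodes)
    return out


def rescale_weights(net: Network) -> Network:
    """Optional min-max rescale of edge weights into (0, 1]. Default off in
    all pipelines — the top challenge method used raw networks."""
    if not net.edges:
        return net
    lo, hi = min(net.edges.values()), max(net.edges.values())
    if hi == lo:
        edges = {e: 1.0 for e in net.edges}
    else:
        # keep weights strictly positive: map [lo, hi] -> (eps, 1]
        eps = 1e-6
        edges = {
            e: eps + (1 - eps) * (w - lo) / (hi - lo) for e, w in net.edges.items()
        }
    out = Network(edges=edges, directed=net.directed)
    out.nodes.update(net.nodes)
    return out


def anonymize(net: Network, seed: int) -> tuple[Network, dict[str, str]]:
    """Random bijective relabeling of gene identifiers (challenge-style).

    Returns the relabeled network and the ``original -> anonymous`` mapping;
    :func:`deanonymize` inverts it.
    """
    rng = random.Random(seed)
    originals = net.node_list()
    codes = [str(i + 1) for i in range(len(originals))]
    rng.shuffle(codes)
    mapping = dict(zip(originals, codes))
    edges = {}
    for (u, v), w in net.edges.items():
        a, b = mapping[u], mapping[v]
        key = (a, b) if net.directed else (min(a, b), max(a, b))
        edges[key] = w
    out = Network(edges=edges, directed=net.directed)
    out.nodes.update(mapping.values())
    return out, mapping


def deanonymize(net: Network, mapping: dict[str, str]) -> Network:
    inverse = {v: k for k, v in mapping.items()}
    edges = {}
    for (u, v), w in net.edges.items():
        a, b = inverse[u], inverse[v]
        key = (a, b) if net.directed else (min(a, b), max(a, b))
        edges[key] = w
    out = Network(edges=edges, directed=net.directed)
    out.nodes.update(inverse[n] for n in net.nodes)
    return out
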