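import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from modulekit.netio import Network


@pytest.fixture
def two_triangles():
    return Network.from_edges(
        [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
         ("d", "e", 1), ("e", "f", 1), ("d", "f", 1)]
    )


@pytest.fixture
def bridged_triangles():
    """Two triangles joined by a single bridge edge."""
    return Network.from_edges(
        [("a", "b", 1), ("b", "c", 1), ("a", "c", 1),
         ("d", "e", 1), ("e", "f", 1), ("d", "f", 1), ("c", "d", 1)]
    )


def hub_cliques(n_cliques=3, size=6, n_spokes=8):
    """A hub wired into every node of several cliques plus bare spokes;
    flow through the hub glues everything into one cluster unless the
    balance penalty intervenes."""
    edges = [("hub", f"s{i:02d}", 1.0) for i in range(n_spokes)]
    for ci in range(n_cliques):
        names = [f"c{ci}_{k}" for k in range(size)]
        for a in range(size):
            for b in range(a + 1, size):
                edges.append((names[a], names[b], 1.0))
            edges.append(("hub", names[a], 1.0))
    return Network.from_edges(edges)


def random_connected_graph(n, p, seed, weighted=True, nonbipartite=False):
    """Erdos-Renyi conditioned on connectivity (resamples until connected).

    With ``nonbipartite=True`` the graph must also contain an odd cycle —
    the regime where the random walk is aperiodic and its visit counts have
    a t -> infinity limit.
    """
    import networkx as nx

    for attempt in range(200):
        rng = np.random.default_rng([seed, attempt])
        triples = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    w = rng.uniform(0.2, 1.0) if weighted else 1.0
                    triples.append((f"n{i:02d}", f"n{j:02d}", w))
        net = Network.from_edges(triples, extra_nodes=[f"n{i:02d}" for i in range(n)])
        if net.n_edges and len(net.connected_components()) == 1:
            if nonbipartite and nx.is_bipartite(net.to_networkx()):
                continue
            return net
    raise RuntimeError("could not sample a connected graph")


def module_ari(truth, predicted, universe):
    """Adjusted Rand index between two module sets over a gene universe;
    unassigned genes count as their own singleton clusters."""
    genes = sorted(universe)
    t_memb = truth.membership()
    p_memb = predicted.membership()
    t_lab = [t_memb.get(g, -1 - i) for i, g in enumerate(genes)]
    p_lab = [p_memb.get(g, -1 - i) for i, g in enumerate(genes)]
    return adjusted_rand_score(t_lab, p_lab)
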