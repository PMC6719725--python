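"""Diffusion state distance (DSD) kernel spectral clustering (method K1).

The distance between two nodes is the L1 distance between their expected
random-walk visit-count vectors. For a walk of ``t`` steps (counting the
starting point as step 0) on the weight-proportional transition operator
``P = D^-1 A``, the visit-count matrix is ``He^t = sum_{s=0..t} P^s``. As
``t -> infinity`` the pairwise L1 row distances converge, and the limit has
the closed form

    DSD(vx, vy) = || (1x - 1y) (I - P + W)^-1 ||_1

where ``W`` has every row equal to pi, the (weighted) node degrees normalized
by the total degree. The DSD matrix is converted to a similarity matrix with
a radial basis function kernel and clustered with normalized spectral
clustering (k-means on the spectral embedding); oversize clusters are split
recursively with k=2 and undersize clusters are discarded, enforcing the
3..100 module-size rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netio import Network, ModuleSet


@dataclass
class K1Params:
    """Parameters of the DSD spectral pipeline.

    k
        number of spectral cluster centers; ``None`` uses ``round(n / 40)``
        (clamped to >= 1), the typical challenge granularity of a few dozen
        genes per module.
    sigma
        RBF bandwidth, or ``"median"`` for the median off-diagonal DSD.
    min_size, max_size
        module-size limits (challenge rules: 3 and 100).
    """

    k: int | None = None
    sigma: float | str = "median"
    min_size: int = 3
    max_size: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_size < 1 or self.max_size < self.min_size:
            raise ValueError("need 1 <= min_size <= max_size")
        if self.sigma != "median" and not float(self.sigma) > 0:
            raise ValueError("sigma must be positive or 'median'")


def _walk_operator(net: Network, order: list[str]) -> np.ndarray:
    a = net.adjacency(order)
    deg = a.sum(axis=1)
    if np.any(deg <= 0):
        bad = order[int(np.argmin(deg))]
        raise ValueError(f"node {bad!r} has zero (out-)degree; network not connected")
    return a / deg[:, None]


def hitting_profile(net: Network, t: int, order: list[str] | None = None) -> np.ndarray:
    """Expected visit counts He^t of a t-step weight-proportional walk.

    Row x holds He^t(vx, .); the walk includes its starting point (0th step),
    so every row sums to t + 1 and ``t=0`` gives the identity.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    order = net.node_list() if order is None else order
    p = _walk_operator(net, order)
    acc = np.eye(len(order))
    power = np.eye(len(order))
    for _ in range(t):
        power = power @ p
        acc += power
    return acc


def dsd_from_profile(profile: np.ndarray) -> np.ndarray:
    """Pairwise L1 distances between rows of a visit-count profile."""
    diff = profile[:, None, :] - profile[None, :, :]
    return np.abs(diff).sum(axis=2)


def dsd_converged(net: Network, order: list[str] | None = None) -> np.ndarray:
    """Converged (t -> infinity) DSD matrix via the resolvent closed form.

    Requires a connected network (for directed input, make it strongly
    connected first). Returns a symmetric zero-diagonal distance matrix in
    canonical node order; DSD is a true metric.
    """
    order = net.node_list() if order is None else order
    n = len(order)
    if n == 1:
        return np.zeros((1, 1))
    comps = net.connected_components()
    if len(comps) > 1:
        raise ValueError(
            f"network has {len(comps)} connected components; "
            "compute DSD per component"
        )
    p = _walk_operator(net, order)
    a = net.adjacency(order)
    deg = a.sum(axis=1)
    pi = deg / deg.sum()
    w = np.tile(pi, (n, 1))
    resolvent = np.linalg.inv(np.eye(n) - p + w)
    return dsd_from_profile(resolvent)


def rbf_similarity(dsd: np.ndarray, sigma: float | str = "median") -> np.ndarray:
    """RBF kernel conversion S = exp(-DSD^2 / (2 sigma^2)) of a DSD matrix."""
    n = dsd.shape[0]
    if sigma == "median":
        if n < 2:
            sigma = 1.0
        else:
            off = dsd[~np.eye(n, dtype=bool)]
            sigma = float(np.median(off))
            if sigma <= 0:
                raise ValueError("degenerate DSD matrix: all distances zero")
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return np.exp(-(dsd**2) / (2 * sigma**2))


def spectral_cluster(kernel: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Cluster a similarity matrix with normalized spectral clustering.

    Ng-Jordan-Weiss style: normalized spectral embedding followed by k-means
    with 10 restarts at a fixed seed. Returns index arrays per cluster
    (empty clusters pruned).
    """
    n = kernel.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n)
    if k == 1:
        return [np.arange(n)]
    if k == n:
        return [np.array([i]) for i in range(n)]
    from sklearn.cluster import SpectralClustering

    sc = SpectralClustering(
        n_clusters=k,
        affinity="precomputed",
        assign_labels="kmeans",
        n_init=10,
        random_state=seed,
    )
    labels = sc.fit_predict(kernel)
    return [np.flatnonzero(labels == c) for c in np.unique(labels)]


def _split_oversize(
    kernel: np.ndarray, idx: np.ndarray, max_size: int, seed: int
) -> list[np.ndarray]:
    """Recursively split an index set with k=2 spectral clustering until all
    parts have at most ``max_size`` members. The kernel is restricted to the
    subcluster rather than re-derived on the induced subgraph."""
    if len(idx) <= max_size:
        return [idx]
    sub = kernel[np.ix_(idx, idx)]
    parts = spectral_cluster(sub, 2, seed=seed)
    if len(parts) < 2 or any(len(p) == 0 for p in parts):
        # degenerate split: halve deterministically to guarantee progress
        half = len(idx) // 2
        parts = [np.arange(half), np.arange(half, len(idx))]
    out: list[np.ndarray] = []
    for p in parts:
        out.extend(_split_oversize(kernel, idx[p], max_size, seed))
    return out


def run_k1(net: Network, params: K1Params | None = None) -> ModuleSet:
    """Full K1 pipeline: DSD -> RBF kernel -> spectral clustering -> size rules.

    Each connected component is processed separately (DSD is only defined
    within a component); the cluster-center budget k is allocated to
    components proportionally to their size. Components smaller than
    ``min_size`` cannot yield a valid module and are skipped.
    """
    params = params or K1Params()
    total_n = net.n_nodes
    k_total = params.k if params.k is not None else max(1, round(total_n / 40))
    comps = [c for c in net.connected_components() if len(c) >= params.min_size]
    modules: list[frozenset[str]] = []
    remaining_k, remaining_n = k_total, sum(len(c) for c in comps)
    for comp in comps:
        share = max(1, round(remaining_k * len(comp) / max(remaining_n, 1)))
        share = min(share, len(comp))
        remaining_k = max(1, remaining_k - share)
        remaining_n -= len(comp)
        order = sorted(comp)
        if len(comp) == 1:
            continue
        sub = net.subgraph(comp)
        dsd = dsd_converged(sub, order)
        kernel = rbf_similarity(dsd, params.sigma)
        clusters = spectral_cluster(kernel, share, seed=params.seed)
        sized: list[np.ndarray] = []
        for idx in clusters:
            sized.extend(_split_oversize(kernel, idx, params.max_size, params.seed))
        for idx in sized:
            if len(idx) >= params.min_size:
                modules.append(frozenset(order[i] for i in idx))
    ms = ModuleSet(modules=modules, method_id="K1")
    ms.validate(params.min_size, params.max_size, universe=net.nodes)
    return ms
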