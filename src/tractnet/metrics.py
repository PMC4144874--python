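"""Weighted nodal and global graph metrics for connectivity backbones.

Conventions
-----------
* The distance between directly connected nodes is the inverse of the edge
  weight, so strong connections are short.
* Clustering uses the Onnela geometric-mean triangle form computed on the
  raw (un-normalised) weights. The resulting "generalised" clustering
  coefficient is not bounded by 1; it is meaningful for comparisons between
  groups rather than as an absolute quantity.
* The characteristic path length is the harmonic-mean length over node
  pairs (reciprocal of the mean reciprocal distance), which stays finite
  when some pairs are disconnected.
* Betweenness centrality counts ordered source-target pairs and is not
  halved; on undirected graphs this is exactly twice the unordered count,
  a constant convention that cancels in any group comparison.
* Disconnected pairs have distance infinity, represented as ``inf``.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

from .network import WeightedNetwork

__all__ = [
    "ShortestPathSolution",
    "GlobalMetricSet",
    "degree_and_strength",
    "generalized_clustering",
    "shortest_paths",
    "path_length_metrics",
    "betweenness",
    "efficiencies",
    "nodal_metrics",
    "global_metrics",
]

#: relative tolerance for treating two path lengths as equal
EQUAL_PATH_RTOL = 1e-12


def degree_and_strength(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Node degree K_i (count of positive-weight edges) and strength S_i
    (sum of incident edge weights)."""
    w = net.weights
    degree = np.count_nonzero(w > 0, axis=1)
    strength = w.sum(axis=1)
    return degree, strength


def generalized_clustering(net: WeightedNetwork) -> tuple[np.ndarray, float]:
    """Onnela-form weighted clustering on raw weights.

    For node i with degree K_i >= 2::

        C_i = 2 / (K_i (K_i - 1)) * sum_{j<h} (w_ij w_ih w_jh)^(1/3)

    over neighbour pairs (j, h) of i; C_i = 0 when K_i < 2. Returns the
    per-node values and their network mean C(G).
    """
    w = net.weights
    degree = np.count_nonzero(w > 0, axis=1)
    cube = np.cbrt(w)
    # diagonal of cube^3 counts each triangle at i twice (ordered j, h)
    tri = np.diagonal(cube @ cube @ cube)
    c = np.zeros(net.n_nodes)
    valid = degree >= 2
    denom = degree * (degree - 1)
    c[valid] = tri[valid] / denom[valid]
    return c, float(c.mean()) if net.n_nodes else 0.0


def _length_graph(net: WeightedNetwork) -> csr_matrix:
    w = net.weights
    lengths = np.zeros_like(w)
    pos = w > 0
    lengths[pos] = 1.0 / w[pos]
    return csr_matrix(lengths)


def _distance_matrix(net: WeightedNetwork) -> np.ndarray:
    if net.n_nodes == 0:
        return np.zeros((0, 0))
    return _csgraph_dijkstra(_length_graph(net), directed=False)


@dataclass(frozen=True)
class ShortestPathSolution:
    """All-pairs shortest paths under inverse-weight distances.

    ``distances[i, j]`` is the shortest-path distance (``inf`` when
    disconnected, 0 on the diagonal); ``sigma[i, j]`` the number of distinct
    shortest i->j paths; ``betweenness_raw[i]`` the ordered-pair Brandes
    accumulation (endpoints excluded, not halved).
    """

    distances: np.ndarray
    sigma: np.ndarray
    betweenness_raw: np.ndarray
    labels: tuple[str, ...]


def shortest_paths(net: WeightedNetwork, rtol: float = EQUAL_PATH_RTOL) -> ShortestPathSolution:
    """Dijkstra/Brandes sweep from every source.

    Path-length ties are detected with relative tolerance ``rtol`` so that
    floating-point sums along equally long routes count as equal shortest
    paths.
    """
    w = net.weights
    n = net.n_nodes
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        row = w[i]
        for j in np.nonzero(row > 0)[0]:
            adj[i].append((int(j), 1.0 / row[j]))

    dist_all = np.full((n, n), np.inf)
    sigma_all = np.zeros((n, n))
    bc = np.zeros(n)

    for s in range(n):
        dist = np.full(n, np.inf)
        sigma = np.zeros(n)
        preds: list[list[int]] = [[] for _ in range(n)]
        dist[s] = 0.0
        sigma[s] = 1.0
        done = np.zeros(n, dtype=bool)
        order: list[int] = []
        heap: list[tuple[float, int]] = [(0.0, s)]
        while heap:
            d, u = heapq.heappop(heap)
            if done[u]:
                continue
            done[u] = True
            order.append(u)
            for v, length in adj[u]:
                nd = d + length
                if nd < dist[v] * (1.0 - rtol):
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif not done[v] and abs(nd - dist[v]) <= rtol * dist[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(n)
        for v in reversed(order):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
        dist_all[s] = dist
        sigma_all[s] = sigma
    return ShortestPathSolution(dist_all, sigma_all, bc, net.labels)


def path_length_metrics(sp: ShortestPathSolution) -> tuple[np.ndarray, float]:
    """Per-node mean shortest path length L_i and harmonic-mean
    characteristic path length L(G).

    L_i is the arithmetic mean of d_ij over j != i (``inf`` if any pair is
    disconnected). L(G) is the reciprocal of the mean reciprocal distance
    over ordered pairs, with 1/inf = 0, so it remains finite on graphs with
    disconnected components.
    """
    d = sp.distances
    n = d.shape[0]
    if n < 2:
        return np.zeros(n), 0.0
    off = ~np.eye(n, dtype=bool)
    l_i = np.array([d[i, off[i]].mean() for i in range(n)])
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    mean_inv = inv[off].mean()
    l_g = float(1.0 / mean_inv) if mean_inv > 0 else float("inf")
    return l_i, l_g


def betweenness(sp: ShortestPathSolution) -> np.ndarray:
    """Nodal betweenness centrality BC_i = sum over ordered pairs (k, j),
    k != i != j, of the fraction of shortest k->j paths through i."""
    return sp.betweenness_raw.copy()


def _global_efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf), 0.0)
    return float(inv[off].mean())


def _floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs inverse-weight distances of a small dense subgraph."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    pos = weights > 0
    d[pos] = 1.0 / weights[pos]
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def efficiencies(net: WeightedNetwork) -> tuple[float, float]:
    """Global and local efficiency under inverse-weight distances.

    E_glob is the mean of 1/d_ij over ordered node pairs. E_loc is the mean
    over nodes of the global efficiency of each node's neighbour-induced
    subgraph (original weights, the node itself excluded); nodes with fewer
    than two neighbours contribute 0.
    """
    w = net.weights
    n = net.n_nodes
    if n == 0:
        return 0.0, 0.0
    e_glob = _global_efficiency_from_distances(_distance_matrix(net))
    e_loc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.nonzero(w[i] > 0)[0]
        if nbrs.size < 2:
            continue
        # neighbour-induced subgraphs are tiny; dense Floyd-Warshall beats
        # sparse Dijkstra here by a wide margin
        e_loc_terms[i] = _global_efficiency_from_distances(
            _floyd_warshall(w[np.ix_(nbrs, nbrs)])
        )
    return e_glob, float(e_loc_terms.mean())


@dataclass(frozen=True)
class GlobalMetricSet:
    """Whole-network summary: mean clustering C(G), harmonic-mean
    characteristic path length L(G), and global/local efficiency."""

    clustering: float
    path_length: float
    global_efficiency: float
    local_efficiency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "clustering": self.clustering,
            "path_length": self.path_length,
            "global_efficiency": self.global_efficiency,
            "local_efficiency": self.local_efficiency,
        }


NODAL_METRIC_COLUMNS = ("degree", "strength", "clustering", "mean_path_length", "betweenness")


def nodal_metrics(net: WeightedNetwork):
    """Per-node metric table: degree, strength, generalised clustering,
    mean shortest path length and betweenness centrality."""
    import pandas as pd

    degree, strength = degree_and_strength(net)
    c_i, _ = generalized_clustering(net)
    sp = shortest_paths(net)
    l_i, _ = path_length_metrics(sp)
    return pd.DataFrame(
        {
            "label": list(net.labels),
            "degree": degree,
            "strength": strength,
            "clustering": c_i,
            "mean_path_length": l_i,
            "betweenness": betweenness(sp),
        }
    )


def global_metrics(net: WeightedNetwork) -> GlobalMetricSet:
    _, c_g = generalized_clustering(net)
    sp_d = _distance_matrix(net)
    n = net.n_nodes
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp_d) & off, 1.0 / np.where(sp_d > 0, sp_d, np.inf), 0.0)
    e_glob = float(inv[off].mean()) if n > 1 else 0.0
    l_g = float(1.0 / e_glob) if e_glob > 0 else float("inf")
    _, e_loc = efficiencies(net)
    return GlobalMetricSet(c_g, l_g, e_glob, e_loc)
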