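"""Independent brute-force oracles for small graphs.

Everything here is deliberately naive (exhaustive enumeration) and shares
no code with the package implementation, so agreement on small random
graphs is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

REL_TOL = 1e-9


def spanning_trees(n: int, edges: list[tuple[int, int, float]]):
    """Yield every spanning tree as a tuple of edge indices."""
    for combo in itertools.combinations(range(len(edges)), n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        for idx in combo:
            i, j, _ = edges[idx]
            ri, rj = find(i), find(j)
            if ri == rj:
                ok = False
                break
            parent[rj] = ri
        if ok:
            yield combo


def max_spanning_tree_weight(n: int, edges: list[tuple[int, int, float]]) -> float:
    """Maximum total weight over all spanning trees (exhaustive)."""
    best = -math.inf
    for combo in spanning_trees(n, edges):
        best = max(best, sum(edges[i][2] for i in combo))
    if best == -math.inf:
        raise ValueError("graph is disconnected")
    return best


def best_spanning_superset_weight(n: int, edges: list[tuple[int, int, float]], size: int) -> float:
    """Max total weight over all edge sets of a given size that contain a
    spanning tree (exhaustive over subsets)."""
    best = -math.inf
    for combo in itertools.combinations(range(len(edges)), size):
        sub = [edges[i] for i in combo]
        # does some subset of this combo span?
        try:
            max_spanning_tree_weight(n, sub)
        except ValueError:
            continue
        best = max(best, sum(e[2] for e in sub))
    if best == -math.inf:
        raise ValueError("no spanning edge set of that size")
    return best


def all_pairs_shortest(weights: np.ndarray):
    """Distances, shortest-path counts and ordered-pair betweenness by
    enumerating every simple path (inverse-weight edge lengths)."""
    n = weights.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    interior: dict[tuple[int, int], list[list[int]]] = {}
    nodes = range(n)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = []
            for k in range(n - 1):
                for mid in itertools.permutations([v for v in nodes if v not in (s, t)], k):
                    seq = (s, *mid, t)
                    length = 0.0
                    ok = True
                    for a, b in zip(seq, seq[1:]):
                        if weights[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / weights[a, b]
                    if ok:
                        paths.append((length, list(mid)))
            if not paths:
                continue
            d = min(p[0] for p in paths)
            shortest = [p for p in paths if p[0] <= d * (1 + REL_TOL)]
            dist[s, t] = d
            sigma[s, t] = len(shortest)
            interior[(s, t)] = [p[1] for p in shortest]
    bc = np.zeros(n)
    for (s, t), mids in interior.items():
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for mid in mids if v in mid)
            bc[v] += through / len(mids)
    return dist, sigma, bc


def clustering_onnela(weights: np.ndarray) -> np.ndarray:
    """Raw-weight Onnela clustering by explicit triangle enumeration."""
    n = weights.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nbrs, 2):
            if weights[j, h] > 0:
                total += (weights[i, j] * weights[i, h] * weights[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * total / (k * (k - 1))
    return c


def global_efficiency(dist: np.ndarray) -> float:
    n = dist.shape[0]
    if n < 2:
        return 0.0
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def local_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        d, _, _ = all_pairs_shortest(sub)
        total += global_efficiency(d)
    return total / n


def harmonic_path_length(dist: np.ndarray) -> float:
    e = global_efficiency(dist)
    return 1.0 / e if e > 0 else math.inf


def random_weighted_graph(rng: np.random.Generator, n: int, density: float = 0.6,
                          connected: bool = False) -> np.ndarray:
    """Random symmetric weighted graph; optionally resampled until connected."""
    while True:
        mask = np.triu(rng.random((n, n)) < density, 1)
        w = np.zeros((n, n))
        w[mask] = rng.uniform(0.2, 5.0, size=int(mask.sum()))
        w = w + w.T
        if not connected:
            return w
        # BFS connectivity check
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for v in range(n):
                if w[u, v] > 0 and v not in seen:
                    seen.add(v)
                    stack.append(v)
        if len(seen) == n:
            return w
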