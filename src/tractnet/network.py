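"""Construction of symmetric weighted networks from directed tract counts.

The stages here mirror how probabilistic-tractography count matrices are
turned into analysable graphs: scans with excessive head motion are dropped,
directed streamline counts are converted to symmetric voxel-normalised edge
weights, repeated scans of a subject are averaged, and a sparse connectivity
backbone (maximum spanning tree plus strongest remaining edges) is extracted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "WeightedNetwork",
    "QCThresholds",
    "BackboneConfig",
    "MotionScreenResult",
    "screen_motion",
    "build_weight_matrix",
    "average_networks",
    "extract_backbone",
]

_SYM_ATOL = 1e-12


def _default_labels(n: int) -> tuple[str, ...]:
    width = max(3, len(str(n)))
    return tuple(f"n{i:0{width}d}" for i in range(1, n + 1))


@dataclass(frozen=True)
class WeightedNetwork:
    """Undirected weighted graph on labelled nodes.

    ``weights`` is a symmetric non-negative matrix with zero diagonal;
    ``weights[i, j]`` is the connection weight between node ``labels[i]``
    and node ``labels[j]`` (0 means no edge).
    """

    weights: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be a square matrix, got shape {w.shape}")
        labels = tuple(self.labels) if self.labels else _default_labels(w.shape[0])
        if len(labels) != w.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {w.shape[0]} nodes"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        scale = max(1.0, float(np.max(w, initial=0.0)))
        if np.max(np.abs(w - w.T), initial=0.0) > _SYM_ATOL * scale:
            raise ValueError("weight matrix must be symmetric")
        w = (w + w.T) / 2.0  # exact symmetry
        np.fill_diagonal(w, 0.0)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_list(self) -> list[tuple[int, int, float]]:
        """Edges as (i, j, weight) with i < j, in lexicographic node order."""
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        return [(int(i), int(j), float(self.weights[i, j])) for i, j in zip(ii, jj)]

    def with_weights(self, weights: np.ndarray) -> "WeightedNetwork":
        return WeightedNetwork(weights, self.labels)


@dataclass(frozen=True)
class QCThresholds:
    """Head-motion exclusion limits: peak absolute translation (mm) and
    rotation (degrees) over all volumes and axes of a scan."""

    max_translation: float = 1.0
    max_rotation: float = 1.0

    def __post_init__(self) -> None:
        if self.max_translation <= 0:
            raise ValueError("max_translation must be strictly positive")
        if self.max_rotation <= 0:
            raise ValueError("max_rotation must be strictly positive")


@dataclass(frozen=True)
class BackboneConfig:
    """Target average node degree K of the connectivity backbone."""

    target_avg_degree: float = 4.0

    def __post_init__(self) -> None:
        if self.target_avg_degree <= 0:
            raise ValueError("target_avg_degree must be strictly positive")


@dataclass(frozen=True)
class MotionScreenResult:
    keep: bool
    reason: str | None
    peak_translation: float
    peak_rotation: float


def screen_motion(log, thresholds: QCThresholds = QCThresholds()) -> MotionScreenResult:
    """Decide whether a scan passes head-motion quality control.

    A scan is excluded when its peak absolute translation exceeds
    ``max_translation`` (default 1 mm) or its peak absolute rotation exceeds
    ``max_rotation`` (default 1 degree), taken over all volumes and axes.
    The returned decision records which rule fired (translation checked
    first).
    """
    params = np.asarray(log.params, dtype=float)
    if params.ndim != 2 or params.shape[1] != 6 or params.shape[0] < 1:
        raise ValueError("motion log must be a non-empty (n_volumes, 6) array")
    if not np.all(np.isfinite(params)):
        raise ValueError("motion log contains non-finite values")
    peak_t = float(np.max(np.abs(params[:, :3])))
    peak_r = float(np.max(np.abs(params[:, 3:])))
    if peak_t > thresholds.max_translation:
        return MotionScreenResult(False, "translation", peak_t, peak_r)
    if peak_r > thresholds.max_rotation:
        return MotionScreenResult(False, "rotation", peak_t, peak_r)
    return MotionScreenResult(True, None, peak_t, peak_r)


def build_weight_matrix(tract_counts, labels: Sequence[str] | None = None) -> WeightedNetwork:
    """Convert directed streamline counts into a symmetric weighted network.

    The weight of the edge between regions i and j is the seed-normalised
    count in both directions::

        w_ij = counts[i, j] / voxels[i] + counts[j, i] / voxels[j]

    so that each directed term is the fraction of pathways seeded in one
    region that reach the other, per seed voxel. Self-connections are
    discarded.
    """
    counts = np.asarray(tract_counts.counts, dtype=float)
    voxels = np.asarray(tract_counts.voxels, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("counts must be a square matrix")
    if voxels.shape != (counts.shape[0],):
        raise ValueError("voxels must have one entry per region")
    if np.any(voxels <= 0):
        bad = np.nonzero(voxels <= 0)[0]
        raise ValueError(f"voxel counts must be strictly positive (regions {bad.tolist()})")
    if np.any(counts < 0):
        raise ValueError("tract counts must be non-negative")
    directed = counts / voxels[:, None]
    w = directed + directed.T
    np.fill_diagonal(w, 0.0)
    if labels is None:
        labels = getattr(tract_counts, "labels", ()) or ()
    return WeightedNetwork(w, tuple(labels))


def average_networks(networks: Sequence[WeightedNetwork]) -> WeightedNetwork:
    """Entrywise arithmetic mean of repeated-scan networks of one subject."""
    if len(networks) == 0:
        raise ValueError("need at least one network to average")
    first = networks[0]
    for net in networks[1:]:
        if net.labels != first.labels:
            raise ValueError("cannot average networks with different node labels")
    mean = np.mean([net.weights for net in networks], axis=0)
    return WeightedNetwork(mean, first.labels)


class DisconnectedGraphError(ValueError):
    """Raised when a backbone is requested for a disconnected network."""

    def __init__(self, components: list[list[str]]):
        self.components = components
        sizes = ", ".join(str(len(c)) for c in components)
        super().__init__(
            f"positive-weight graph is disconnected ({len(components)} components "
            f"of sizes {sizes}); components: {components}"
        )


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _components(n: int, edges: list[tuple[int, int, float]]) -> list[list[int]]:
    uf = _UnionFind(n)
    for i, j, _ in edges:
        uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for v in range(n):
        groups.setdefault(uf.find(v), []).append(v)
    return sorted(groups.values(), key=lambda g: (-len(g), g))


def extract_backbone(
    net: WeightedNetwork, config: BackboneConfig = BackboneConfig()
) -> WeightedNetwork:
    """Extract the connectivity backbone of a weighted network.

    A maximum spanning tree is found first (so the backbone connects every
    node), then the remaining edges are added in descending weight order
    until the network holds ``floor(N * K / 2)`` edges, i.e. average node
    degree K. Kept edges retain their original weights; all other entries
    become zero. Ties in weight are broken by lexicographic (i, j) node-pair
    order so the result is deterministic.
    """
    n = net.n_nodes
    k = config.target_avg_degree
    if k < 2.0 * (n - 1) / n:
        raise ValueError(
            f"target_avg_degree={k} too small to hold a spanning tree on {n} nodes "
            f"(need at least {2.0 * (n - 1) / n:.4g})"
        )
    target = math.floor(n * k / 2.0)
    edges = net.edge_list()
    # sort by descending weight, lexicographic (i, j) tie-break
    order = sorted(edges, key=lambda e: (-e[2], e[0], e[1]))
    uf = _UnionFind(n)
    tree: list[tuple[int, int, float]] = []
    rest: list[tuple[int, int, float]] = []
    for i, j, w in order:
        if uf.union(i, j):
            tree.append((i, j, w))
        else:
            rest.append((i, j, w))
    if len(tree) < n - 1:
        comps = _components(n, edges)
        raise DisconnectedGraphError([[net.labels[v] for v in c] for c in comps])
    if len(edges) < target:
        raise ValueError(
            f"network has only {len(edges)} positive edges; backbone needs {target}"
        )
    kept = tree + rest[: target - len(tree)]
    out = np.zeros_like(net.weights)
    for i, j, w in kept:
        out[i, j] = out[j, i] = w
    return WeightedNetwork(out, net.labels)
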