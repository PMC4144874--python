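"""Degree-preserving rewired null models and small-world assessment.

Random reference networks are produced by Markov-chain edge swapping
(Maslov-Sneppen): repeatedly pick two edges (a, b) and (c, d) and exchange
their endpoints to (a, d) and (c, b), rejecting swaps that would create a
self-loop or duplicate edge. Each node keeps its degree and each edge
carries its weight with it, so the degree sequence and the weight multiset
are conserved while all other structure is randomised. Connectivity is not
enforced; the efficiency metrics tolerate disconnected null networks
through the infinite-distance convention.

A network is classified as small-world when its global efficiency is close
to (but below) the mean of a matched random ensemble while its local
efficiency is much greater.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import efficiencies
from .network import WeightedNetwork

__all__ = ["SmallWorldResult", "rewire_preserving_degree", "small_world_assessment"]


@dataclass(frozen=True)
class SmallWorldResult:
    """Efficiency ratios of a network against its rewired ensemble."""

    eglob_ratio: float
    eloc_ratio: float
    ensemble_size: int
    eglob: float
    eloc: float
    eglob_random: float
    eloc_random: float
    is_small_world: bool

    def as_dict(self) -> dict[str, float | int | bool]:
        return {
            "eglob_ratio": self.eglob_ratio,
            "eloc_ratio": self.eloc_ratio,
            "ensemble_size": self.ensemble_size,
            "eglob": self.eglob,
            "eloc": self.eloc,
            "eglob_random": self.eglob_random,
            "eloc_random": self.eloc_random,
            "is_small_world": self.is_small_world,
        }


def rewire_preserving_degree(
    net: WeightedNetwork, n_swap_per_edge: int = 10, seed: int = 0
) -> WeightedNetwork:
    """Markov-chain degree-preserving rewiring.

    Attempts ``n_swap_per_edge * M`` swaps on the M edges. Deterministic for
    a given seed. If the network has fewer than two edges no swap is
    possible; the input is returned with a warning.
    """
    edges = net.edge_list()
    m = len(edges)
    if m < 2:
        warnings.warn("network has fewer than 2 edges; returning it unchanged")
        return net
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    present = {(i, j) for i, j, _ in edges}
    edge_arr = [[i, j, w] for i, j, w in edges]
    n_attempts = int(n_swap_per_edge) * m
    for _ in range(n_attempts):
        e1, e2 = rng.integers(0, m, size=2)
        if e1 == e2:
            continue
        a, b, w1 = edge_arr[e1]
        c, d, w2 = edge_arr[e2]
        if rng.random() < 0.5:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1 = (min(a, d), max(a, d))
        new2 = (min(c, b), max(c, b))
        if new1 in present or new2 in present or new1 == new2:
            continue
        present.discard((min(a, b), max(a, b)))
        present.discard((min(c, d), max(c, d)))
        present.add(new1)
        present.add(new2)
        edge_arr[e1] = [new1[0], new1[1], w1]
        edge_arr[e2] = [new2[0], new2[1], w2]
    out = np.zeros_like(net.weights)
    for i, j, w in edge_arr:
        out[i, j] = out[j, i] = w
    return WeightedNetwork(out, net.labels)


def small_world_assessment(
    net: WeightedNetwork,
    ensemble_size: int = 100,
    n_swap_per_edge: int = 10,
    margin: float = 1.0,
    seed: int = 0,
) -> SmallWorldResult:
    """Compare a network's efficiencies with a degree-matched random ensemble.

    Generates ``ensemble_size`` rewired networks (member k drawn from a
    stream keyed by (seed, k)), averages their global and local efficiency,
    and reports the ratios E_glob(G)/E_glob(G_random) and
    E_loc(G)/E_loc(G_random). The network is classified small-world when
    the global ratio is below 1 while the local ratio exceeds ``margin``
    (default 1; "much greater" is deliberately left as a tunable threshold).
    """
    if ensemble_size < 1:
        raise ValueError("ensemble_size must be at least 1")
    e_glob, e_loc = efficiencies(net)
    glob_rand = np.empty(ensemble_size)
    loc_rand = np.empty(ensemble_size)
    for k in range(ensemble_size):
        member_seed = np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2**31)
        member = rewire_preserving_degree(net, n_swap_per_edge, int(member_seed))
        glob_rand[k], loc_rand[k] = efficiencies(member)
    mean_glob = float(glob_rand.mean())
    mean_loc = float(loc_rand.mean())
    if mean_glob > 0:
        eglob_ratio = e_glob / mean_glob
    else:
        warnings.warn("random ensemble has zero mean global efficiency")
        eglob_ratio = float("inf")
    if mean_loc > 0:
        eloc_ratio = e_loc / mean_loc
    else:
        warnings.warn("random ensemble has zero mean local efficiency")
        eloc_ratio = float("inf")
    return SmallWorldResult(
        eglob_ratio=float(eglob_ratio),
        eloc_ratio=float(eloc_ratio),
        ensemble_size=ensemble_size,
        eglob=e_glob,
        eloc=e_loc,
        eglob_random=mean_glob,
        eloc_random=mean_loc,
        is_small_world=bool(eglob_ratio < 1.0 and eloc_ratio > margin),
    )
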