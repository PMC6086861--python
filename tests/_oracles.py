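"""Independent brute-force reference implementations used only by tests.

Deliberately naive (triple loops, explicit triangle enumeration) and
independent of the package's vectorized/scipy code paths.
"""

from __future__ import annotations

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/weight, O(n^3) loops."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def strength_brute(weights: np.ndarray) -> np.ndarray:
    n = weights.shape[0]
    return np.array([sum(weights[i, j] for j in range(n)) for i in range(n)])


def onnela_clustering_brute(weights: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering by explicit triangle enumeration."""
    n = weights.shape[0]
    wmax = weights.max()
    out = np.zeros(n)
    if wmax == 0:
        return out
    for i in range(n):
        neighbors = [j for j in range(n) if weights[i, j] > 0]
        k = len(neighbors)
        if k < 2:
            continue
        total = 0.0
        for j in neighbors:
            for h in neighbors:
                if j == h or weights[j, h] == 0:
                    continue
                total += ((weights[i, j] / wmax) * (weights[j, h] / wmax)
                          * (weights[h, i] / wmax)) ** (1.0 / 3.0)
        out[i] = total / (k * (k - 1))
    return out


def harmonic_closeness_brute(weights: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weights)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        s = 0.0
        for j in range(n):
            if j != i and np.isfinite(d[i, j]) and d[i, j] > 0:
                s += 1.0 / d[i, j]
        out[i] = s / (n - 1)
    return out


def global_efficiency_brute(weights: np.ndarray) -> float:
    return float(harmonic_closeness_brute(weights).mean())


def char_path_length_brute(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = d.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals))


def random_weighted_graph(rng: np.random.Generator, n_nodes: int,
                          density: float = 0.3) -> np.ndarray:
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    mask = rng.random(len(iu[0])) < density
    vals = rng.uniform(0.05, 1.0, size=len(iu[0])) * mask
    w[iu] = vals
    w += w.T
    return w
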