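"""Independent brute-force oracles used to validate the fast implementations.

Everything here is written as plainly as possible (explicit loops, direct
definitions) and stays independent of the code paths it checks.
"""
from __future__ import annotations

import numpy as np


def floyd_warshall(weights: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths with edge length 1/weight, by triple loop."""
    n = weights.shape[0]
    d = np.full((n, n), np.inf)
    for i in range(n):
        d[i, i] = 0.0
        for j in range(n):
            if i != j and weights[i, j] > 0:
                d[i, j] = 1.0 / weights[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_efficiency(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = d.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def nodal_efficiency(weights: np.ndarray) -> np.ndarray:
    d = floyd_warshall(weights)
    n = d.shape[0]
    out = np.zeros(n)
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]) and d[i, j] > 0:
                out[i] += 1.0 / d[i, j]
        out[i] /= n - 1
    return out


def char_path_length(weights: np.ndarray) -> float:
    d = floyd_warshall(weights)
    n = d.shape[0]
    finite = [d[i, j] for i in range(n) for j in range(n) if i != j and np.isfinite(d[i, j])]
    return float(np.mean(finite)) if finite else 0.0


def onnela_clustering(weights: np.ndarray) -> float:
    """Mean Onnela clustering by direct triangle enumeration."""
    n = weights.shape[0]
    mx = weights.max()
    if mx == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                u, v = nbrs[a], nbrs[b]
                if weights[u, v] > 0:
                    s += (
                        (weights[i, u] / mx) * (weights[i, v] / mx) * (weights[u, v] / mx)
                    ) ** (1.0 / 3.0)
        total += 2.0 * s / (k * (k - 1))
    return total / n


def local_efficiency(weights: np.ndarray) -> float:
    n = weights.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        if len(nbrs) < 2:
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        total += global_efficiency(sub)
    return total / n


def degrees(weights: np.ndarray) -> np.ndarray:
    return np.array([sum(1 for j in range(weights.shape[0]) if weights[i, j] > 0)
                     for i in range(weights.shape[0])])


def phi_w(weights: np.ndarray, k: int) -> float:
    """Weighted rich-club coefficient by explicit subgraph + full weight sort."""
    n = weights.shape[0]
    deg = degrees(weights)
    club = [i for i in range(n) if deg[i] > k]
    club_weights = [
        weights[i, j] for ai, i in enumerate(club) for j in club[ai + 1:] if weights[i, j] > 0
    ]
    if not club_weights:
        return float("nan")
    all_weights = sorted(
        (weights[i, j] for i in range(n) for j in range(i + 1, n) if weights[i, j] > 0),
        reverse=True,
    )
    return sum(club_weights) / sum(all_weights[: len(club_weights)])


def random_weighted_graph(n: int, density: float, rng: np.random.Generator) -> np.ndarray:
    w = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                w[i, j] = w[j, i] = rng.uniform(0.1, 5.0)
    return w
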