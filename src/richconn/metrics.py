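"""Global and nodal graph metrics with random-network normalization.

Conventions (standard for weighted structural connectomes):

* Edge length is the reciprocal weight, ``l_ij = 1 / w_ij``; distances are
  shortest path lengths over these lengths, +inf for disconnected pairs.
* Global efficiency Eg is the mean of ``1 / d_ij`` over ordered node pairs
  (0 for disconnected pairs); nodal efficiency is the per-node row mean.
* Characteristic path length Lp averages only the finite distances.
* Clustering uses the Onnela geometric-mean formula with weights normalized
  by the network maximum; it reduces to the binary triangle fraction when
  all weights are equal.
* Local efficiency Eloc is the mean over nodes of the global efficiency of
  the subgraph induced by each node's neighbours.
* gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>, sigma = gamma / lambda,
  where the null ensemble consists of Maslov-Sneppen degree-preserving
  rewirings with the weight multiset randomly reassigned to the rewired
  edges.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .netbuild import WeightedNetwork, apply_sparsity


@dataclass
class GlobalMetrics:
    cp: float
    lp: float
    eg: float
    eloc: float
    gamma: float | None = None
    lam: float | None = None
    sigma: float | None = None


@dataclass
class SmallWorldIndices:
    gamma: float
    lam: float
    sigma: float
    cp: float
    lp: float
    cp_null: np.ndarray
    lp_null: np.ndarray
    undefined: bool = False


@dataclass
class MetricCurve:
    metric: str
    sparsity_grid: np.ndarray
    values: np.ndarray
    auc: float


def distance_matrix(network: WeightedNetwork) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    w = network.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    d = shortest_path(csr_matrix(lengths), method="D", directed=False)
    np.fill_diagonal(d, 0.0)
    return d


def _efficiency_from_distances(d: np.ndarray) -> tuple[float, np.ndarray]:
    n = d.shape[0]
    if n < 2:
        return 0.0, np.zeros(n)
    inv = np.zeros_like(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & (d > 0)
    inv[finite] = 1.0 / d[finite]
    nodal = inv.sum(axis=1) / (n - 1)
    return float(nodal.mean()), nodal


def _char_path_length(d: np.ndarray) -> float:
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = d[off][np.isfinite(d[off])]
    return float(finite.mean()) if finite.size else 0.0


def binary_degrees(weights: np.ndarray) -> np.ndarray:
    return np.count_nonzero(weights > 0, axis=1)


def clustering_onnela(weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean and per-node Onnela weighted clustering coefficient."""
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    mx = w.max()
    if mx == 0:
        return 0.0, np.zeros(n)
    wh = np.cbrt(w / mx)
    tri = np.einsum("ij,jk,ki->i", wh, wh, wh)  # = 2 * triangle intensity
    k = binary_degrees(w)
    denom = k * (k - 1)
    c = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    return float(c.mean()), c


def global_efficiency(network: WeightedNetwork) -> float:
    return _efficiency_from_distances(distance_matrix(network))[0]


def nodal_efficiency(network: WeightedNetwork) -> np.ndarray:
    return _efficiency_from_distances(distance_matrix(network))[1]


def local_efficiency(network: WeightedNetwork) -> float:
    """Mean over nodes of Eg of the neighbour-induced weighted subgraph."""
    w = network.weights
    n = w.shape[0]
    total = 0.0
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        total += _efficiency_from_distances(
            shortest_path(csr_matrix(_inverse_lengths(sub)), method="D", directed=False)
        )[0]
    return total / n if n else 0.0


def _inverse_lengths(w: np.ndarray) -> np.ndarray:
    return np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)


def compute_global_metrics(network: WeightedNetwork) -> GlobalMetrics:
    """Raw Cp, Lp, Eg and Eloc of a weighted network (no normalization)."""
    if network.n_nodes < 2:
        raise ValueError("network must have at least 2 nodes")
    d = distance_matrix(network)
    eg, _ = _efficiency_from_distances(d)
    cp, _ = clustering_onnela(network.weights)
    return GlobalMetrics(
        cp=cp,
        lp=_char_path_length(d),
        eg=eg,
        eloc=local_efficiency(network),
    )


def compute_nodal_metrics(network: WeightedNetwork) -> dict[str, np.ndarray]:
    d = distance_matrix(network)
    _, nodal = _efficiency_from_distances(d)
    return {
        "degree": binary_degrees(network.weights),
        "strength": network.weights.sum(axis=1),
        "nodal_efficiency": nodal,
    }


# ---------------------------------------------------------------------------
# Degree-preserving null model
# ---------------------------------------------------------------------------

def _maslov_sneppen_edges(
    ei: list[int], ej: list[int], n_nodes: int, n_swaps: int, rng: np.random.Generator
) -> tuple[list[int], list[int], int]:
    """Double-edge swaps on an undirected edge list; preserves all degrees."""
    E = len(ei)
    enc = n_nodes
    eset = {a * enc + b for a, b in zip(ei, ej)}
    swaps = 0
    tries = 0
    max_tries = 60 * n_swaps + 200
    block = 4096
    while swaps < n_swaps and tries < max_tries:
        r1 = rng.integers(0, E, block).tolist()
        r2 = rng.integers(0, E, block).tolist()
        flip = (rng.random(block) < 0.5).tolist()
        for x, y, f in zip(r1, r2, flip):
            if swaps >= n_swaps or tries >= max_tries:
                break
            tries += 1
            if x == y:
                continue
            a, b = ei[x], ej[x]
            c, d = ei[y], ej[y]
            if f:
                c, d = d, c
            # propose (a,b),(c,d) -> (a,d),(c,b)
            if a == c or a == d or b == c or b == d:
                continue
            n1a, n1b = (a, d) if a < d else (d, a)
            n2a, n2b = (c, b) if c < b else (b, c)
            k1 = n1a * enc + n1b
            k2 = n2a * enc + n2b
            if k1 in eset or k2 in eset:
                continue
            eset.remove(a * enc + b)
            eset.remove((c * enc + d) if c < d else (d * enc + c))
            eset.add(k1)
            eset.add(k2)
            ei[x], ej[x] = n1a, n1b
            ei[y], ej[y] = n2a, n2b
            swaps += 1
    return ei, ej, swaps


def rewire_null(
    network: WeightedNetwork,
    n_swaps_per_edge: int = 10,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> WeightedNetwork:
    """Degree-matched random network.

    Maslov-Sneppen double-edge swaps randomize the binary topology while
    preserving every node's degree exactly; the multiset of original edge
    weights is then reassigned to the rewired edges in random order. With
    fewer than 2 edges the input is returned unchanged with a
    ``rewire_warning`` flag.
    """
    n = network.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = network.weights[iu, ju]
    present = w > 0
    if present.sum() < 2:
        out = network.copy()
        out.flags["rewire_warning"] = True
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ei = iu[present].tolist()
    ej = ju[present].tolist()
    weights = w[present]
    n_swaps = n_swaps_per_edge * len(ei)
    ei, ej, _ = _maslov_sneppen_edges(ei, ej, n, n_swaps, rng)
    new = np.zeros_like(network.weights)
    new[np.array(ei), np.array(ej)] = weights[rng.permutation(len(weights))]
    new = new + new.T
    return WeightedNetwork(new, atlas=network.atlas)


def small_world_indices(
    network: WeightedNetwork,
    n_null: int = 1000,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
) -> SmallWorldIndices:
    """gamma, lambda and sigma against degree-preserving rewired nulls."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    base = compute_global_metrics(network)
    rng = np.random.default_rng(seed)
    cp_null = np.empty(n_null)
    lp_null = np.empty(n_null)
    for i in range(n_null):
        null = rewire_null(network, n_swaps_per_edge=n_swaps_per_edge, seed=rng)
        d = distance_matrix(null)
        cp_null[i] = clustering_onnela(null.weights)[0]
        lp_null[i] = _char_path_length(d)
    mean_cp = cp_null.mean()
    mean_lp = lp_null.mean()
    if mean_cp == 0 or mean_lp == 0:
        return SmallWorldIndices(
            np.nan, np.nan, np.nan, base.cp, base.lp, cp_null, lp_null, undefined=True
        )
    gamma = base.cp / mean_cp
    lam = base.lp / mean_lp
    return SmallWorldIndices(gamma, lam, gamma / lam, base.cp, base.lp, cp_null, lp_null)


# ---------------------------------------------------------------------------
# Sparsity curves
# ---------------------------------------------------------------------------

_METRIC_FUNCS = {
    "cp": lambda net: clustering_onnela(net.weights)[0],
    "lp": lambda net: _char_path_length(distance_matrix(net)),
    "eg": global_efficiency,
    "eloc": local_efficiency,
}


def sparsity_grid(start: float = 0.10, stop: float = 0.40, step: float = 0.01) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def sparsity_auc(
    network: WeightedNetwork, metric: str, grid: np.ndarray | None = None
) -> MetricCurve:
    """Metric evaluated across sparsity thresholds with trapezoidal AUC."""
    name = metric.lower()
    if name not in _METRIC_FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_METRIC_FUNCS)}")
    if grid is None:
        grid = sparsity_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending with >= 2 points")
    if grid[0] <= 0 or grid[-1] > 1:
        raise ValueError("grid values must lie in (0, 1]")
    func = _METRIC_FUNCS[name]
    values = np.array([func(apply_sparsity(network, s)) for s in grid])
    auc = float(np.trapezoid(values, grid))
    return MetricCurve(name, grid, values, auc)
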