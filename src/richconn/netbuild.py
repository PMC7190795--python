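"""Weighted-network construction from tractography ingredients.

A subject's raw connectome consists of a streamline-count matrix (FN), a
mean-FA matrix and per-node volumes. The analysis weight of an edge is

    w_ij = FN_ij * FA_ij / ((vol_i + vol_j) / 2)       for FN_ij >= threshold

i.e. the streamline count scaled by mean fractional anisotropy and
normalized by the average volume of the two connected regions. Group-level
consensus backbones retain edges present in at least a given fraction of
subjects.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .atlas import NodeAtlas

_SYM_TOL = 1e-9


def _check_symmetric(m: np.ndarray, what: str) -> None:
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{what} must be a square matrix")
    if not np.allclose(m, m.T, atol=_SYM_TOL, rtol=0):
        raise ValueError(f"{what} must be symmetric")


@dataclass(eq=False)
class RawConnectome:
    """Per-subject streamline counts, mean FA and node volumes."""

    fn: np.ndarray
    fa: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.fn = np.asarray(self.fn)
        self.fa = np.asarray(self.fa, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        _check_symmetric(self.fn, "FN")
        _check_symmetric(self.fa, "FA")
        n = self.fn.shape[0]
        if self.fa.shape != (n, n) or self.volumes.shape != (n,):
            raise ValueError("FN, FA and volumes have inconsistent shapes")
        if np.any(self.fn < 0):
            raise ValueError("FN must be non-negative")
        if np.any(np.diag(self.fn) != 0) or np.any(np.diag(self.fa) != 0):
            raise ValueError("FN and FA must have zero diagonals")
        if np.any(self.volumes <= 0):
            raise ValueError("node volumes must be strictly positive")
        if np.any((self.fa > 0) != (self.fn > 0)):
            raise ValueError("FA support must equal FN support")
        if np.any(self.fa < 0) or np.any(self.fa > 1):
            raise ValueError("FA values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return self.fn.shape[0]


@dataclass(eq=False)
class WeightedNetwork:
    """Symmetric non-negative weighted adjacency matrix with zero diagonal."""

    weights: np.ndarray
    atlas: NodeAtlas | None = None
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        _check_symmetric(w, "weights")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have a zero diagonal")
        # enforce exact symmetry so downstream code can rely on it
        iu = np.triu_indices(w.shape[0], k=1)
        sym = np.zeros_like(w)
        sym[iu] = w[iu]
        self.weights = sym + sym.T

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices(self.n_nodes, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def copy(self) -> "WeightedNetwork":
        return WeightedNetwork(self.weights.copy(), self.atlas, dict(self.flags))


@dataclass(eq=False)
class ConsensusBackbone:
    """Group-level backbone: edge support mask plus mean weights."""

    mask: np.ndarray
    weights: np.ndarray
    prevalence_threshold: float
    atlas: NodeAtlas | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.weights = np.asarray(self.weights, dtype=float)
        _check_symmetric(self.mask.astype(float), "mask")
        if np.any(np.diag(self.mask)):
            raise ValueError("mask must have a zero diagonal")
        if np.any(self.weights[~self.mask] != 0):
            raise ValueError("weights must be zero off the mask")

    def to_network(self, binary: bool = False) -> WeightedNetwork:
        w = self.mask.astype(float) if binary else self.weights
        return WeightedNetwork(w, atlas=self.atlas)


def build_network(
    raw: RawConnectome, fn_threshold: int = 1, atlas: NodeAtlas | None = None
) -> WeightedNetwork:
    """Construct the weighted network ``w = FN * FA / mean volume``.

    Edges with ``FN < fn_threshold`` are removed; the volume denominator is
    the arithmetic mean of the two endpoint volumes.
    """
    if fn_threshold < 1:
        raise ValueError("fn_threshold must be >= 1")
    vol_pair = (raw.volumes[:, None] + raw.volumes[None, :]) / 2.0
    w = np.where(raw.fn >= fn_threshold, raw.fn * raw.fa, 0.0) / vol_pair
    np.fill_diagonal(w, 0.0)
    return WeightedNetwork(w, atlas=atlas)


def group_consensus(
    networks: Sequence[WeightedNetwork], prevalence: float
) -> ConsensusBackbone:
    """Backbone of edges present (w > 0) in at least ``prevalence`` of subjects.

    Retained edge weight is the mean weight over the subjects in which the
    edge is present.
    """
    if len(networks) == 0:
        raise ValueError("at least one network is required")
    if not 0 < prevalence <= 1:
        raise ValueError("prevalence must be in (0, 1]")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("all networks must have the same number of nodes")
    stack = np.stack([net.weights for net in networks])
    present = stack > 0
    count = present.sum(axis=0)
    frac = count / len(networks)
    mask = frac >= prevalence - 1e-12
    np.fill_diagonal(mask, False)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_present = np.where(count > 0, stack.sum(axis=0) / np.maximum(count, 1), 0.0)
    weights = np.where(mask, mean_present, 0.0)
    return ConsensusBackbone(mask, weights, prevalence, atlas=networks[0].atlas)


def apply_sparsity(network: WeightedNetwork, s: float) -> WeightedNetwork:
    """Keep the ``round(s * N(N-1)/2)`` largest-weight edges, zeroing the rest.

    Rounding is half-away-from-zero; ties at the cut are broken by lowest
    (i, j) lexicographic edge index so the result is deterministic.
    """
    if not 0 < s <= 1:
        raise ValueError("sparsity must be in (0, 1]")
    n = network.n_nodes
    e_max = n * (n - 1) // 2
    m = int(np.floor(s * e_max + 0.5))
    iu, ju = np.triu_indices(n, k=1)
    w = network.weights[iu, ju]
    order = np.lexsort((ju, iu, -w))
    keep = order[:m]
    keep = keep[w[keep] > 0]  # zero entries are not edges
    out = np.zeros_like(network.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return WeightedNetwork(out, atlas=network.atlas)
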