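"""Weighted rich-club curves, rich-node identification and edge classes.

The weighted rich-club coefficient at degree level k is

    Phi_w(k) = W_{>k} / sum of the E_{>k} largest edge weights network-wide,

where W_{>k} and E_{>k} are the total weight and count of edges whose two
endpoints both have binary degree > k. Phi_w is normalized by its mean over
degree-preserving rewired null networks; Phi_norm(k) > 1 over a range of k
indicates rich-club organization.

Edges are partitioned by the rich-node set into rich-club (both endpoints
rich), feeder (exactly one endpoint rich) and local (neither) connections.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .atlas import NodeAtlas
from .netbuild import WeightedNetwork
from .metrics import binary_degrees, rewire_null

CLASS_NAMES = ("rich-club", "feeder", "local")


@dataclass
class RichClubCurve:
    k_grid: np.ndarray
    phi_w: np.ndarray           # nan where undefined (no club edges)
    phi_null_mean: np.ndarray
    phi_null_sd: np.ndarray
    phi_norm: np.ndarray        # nan where the null mean is 0/undefined
    n_null: int
    seed: int | None


@dataclass
class EdgeClassification:
    rich_nodes: frozenset
    edge_class: dict            # (i, j) with i < j -> class name
    class_strength: dict        # class name -> summed weight
    ratios: dict                # "rich/feeder", "rich/local" (nan if undefined)


def binary_degree(network: WeightedNetwork) -> np.ndarray:
    """Number of binary connections per node (weights ignored)."""
    return binary_degrees(network.weights)


def _phi_curve(weights: np.ndarray, k_grid: np.ndarray) -> np.ndarray:
    """Vectorised Phi_w over a k grid (nan where no club edges exist)."""
    n = weights.shape[0]
    deg = binary_degrees(weights)
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    present = w > 0
    sorted_desc = np.sort(w[present])[::-1]
    cum = np.concatenate([[0.0], np.cumsum(sorted_desc)])
    phi = np.full(len(k_grid), np.nan)
    for idx, k in enumerate(k_grid):
        in_club = deg > k
        club_edge = present & in_club[iu] & in_club[ju]
        e = int(club_edge.sum())
        if e == 0:
            continue
        phi[idx] = w[club_edge].sum() / cum[e]
    return phi


def rich_club_coefficient(network: WeightedNetwork, k: int) -> float:
    """Weighted rich-club coefficient Phi_w(k); nan if the club has no edges."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return float(_phi_curve(network.weights, np.array([k]))[0])


def normalized_rich_club(
    network: WeightedNetwork,
    k_grid: Sequence[int] | None = None,
    n_null: int = 1000,
    seed: int | None = None,
    n_swaps_per_edge: int = 10,
) -> RichClubCurve:
    """Phi_w(k) together with its degree-preserving null normalization."""
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    deg = binary_degree(network)
    if k_grid is None:
        kmax = int(deg.max()) if deg.size else 0
        k_grid = np.arange(1, max(kmax, 2))
    k_grid = np.asarray(k_grid, dtype=int)
    phi = _phi_curve(network.weights, k_grid)
    rng = np.random.default_rng(seed)
    null_phi = np.full((n_null, len(k_grid)), np.nan)
    for i in range(n_null):
        null = rewire_null(network, n_swaps_per_edge=n_swaps_per_edge, seed=rng)
        null_phi[i] = _phi_curve(null.weights, k_grid)
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(null_phi), axis=0)
        mean = np.where(all_nan, np.nan, np.nanmean(np.where(all_nan, 0.0, null_phi), axis=0))
        sd = np.where(all_nan, np.nan, np.nanstd(np.where(all_nan, 0.0, null_phi), axis=0))
        norm = np.where((mean != 0) & ~np.isnan(mean), phi / mean, np.nan)
    return RichClubCurve(k_grid, phi, mean, sd, norm, n_null, seed)


def identify_rich_nodes(
    network: WeightedNetwork, k: int | None = None, top_n: int | None = None
) -> frozenset:
    """Rich nodes either by degree cutoff (> k) or as the top-n by degree.

    In top-n mode ties are broken by strength, then by node index, so the
    selection is deterministic.
    """
    if (k is None) == (top_n is None):
        raise ValueError("provide exactly one of k or top_n")
    deg = binary_degree(network)
    if k is not None:
        if k < 0:
            raise ValueError("k must be non-negative")
        return frozenset(np.flatnonzero(deg > k).tolist())
    if not 0 < top_n <= network.n_nodes:
        raise ValueError("top_n must be in 1..n_nodes")
    strength = network.weights.sum(axis=1)
    order = np.lexsort((np.arange(len(deg)), -strength, -deg))
    return frozenset(order[:top_n].tolist())


def classify_edges(network: WeightedNetwork, rich_nodes: Iterable[int]) -> EdgeClassification:
    """Partition existing edges into rich-club / feeder / local classes."""
    rich = frozenset(int(i) for i in rich_nodes)
    n = network.n_nodes
    if rich and (min(rich) < 0 or max(rich) >= n):
        raise ValueError("rich node ids outside the network")
    is_rich = np.zeros(n, dtype=bool)
    is_rich[list(rich)] = True
    iu, ju = np.triu_indices(n, k=1)
    w = network.weights[iu, ju]
    present = w > 0
    n_rich_ends = is_rich[iu].astype(int) + is_rich[ju].astype(int)
    edge_class = {}
    strengths = dict.fromkeys(CLASS_NAMES, 0.0)
    for cls, ends in zip(CLASS_NAMES, (2, 1, 0)):
        sel = present & (n_rich_ends == ends)
        strengths[cls] = float(w[sel].sum())
        for a, b in zip(iu[sel].tolist(), ju[sel].tolist()):
            edge_class[(a, b)] = cls
    ratios = {
        "rich/feeder": strengths["rich-club"] / strengths["feeder"]
        if strengths["feeder"] > 0
        else float("nan"),
        "rich/local": strengths["rich-club"] / strengths["local"]
        if strengths["local"] > 0
        else float("nan"),
    }
    return EdgeClassification(rich, edge_class, strengths, ratios)


def class_strengths_matrix(weights: np.ndarray, rich_mask: np.ndarray) -> np.ndarray:
    """(rich, feeder, local) strength sums for one weight matrix (fast path)."""
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = weights[iu, ju]
    ends = rich_mask[iu].astype(int) + rich_mask[ju].astype(int)
    return np.array([w[ends == 2].sum(), w[ends == 1].sum(), w[ends == 0].sum()])


def subject_class_strengths(
    networks: Sequence[WeightedNetwork], rich_nodes: Iterable[int]
) -> pd.DataFrame:
    """Per-subject rich-club / feeder / local strength sums.

    The rich-node set (typically derived from the group consensus backbone)
    is applied to every subject's individual network; the resulting three
    strengths per subject feed the group tests and clinical correlations.
    """
    rich = frozenset(int(i) for i in rich_nodes)
    if not networks:
        raise ValueError("at least one network is required")
    n = networks[0].n_nodes
    if any(net.n_nodes != n for net in networks):
        raise ValueError("all networks must share the atlas size")
    if rich and (min(rich) < 0 or max(rich) >= n):
        raise ValueError("rich node ids outside the network")
    mask = np.zeros(n, dtype=bool)
    mask[list(rich)] = True
    rows = [class_strengths_matrix(net.weights, mask) for net in networks]
    return pd.DataFrame(rows, columns=["rich_club", "feeder", "local"])


def export_brainnet(
    network: WeightedNetwork,
    rich_nodes: Iterable[int],
    atlas: NodeAtlas,
    node_path,
    edge_path,
) -> None:
    """Write BrainNet Viewer ``.node`` / ``.edge`` files.

    ``.node``: six whitespace-delimited columns x y z color size label, with
    color 1 for rich nodes and 2 otherwise and size = nodal strength.
    ``.edge``: the full N x N weight matrix.
    """
    rich = set(int(i) for i in rich_nodes)
    strength = network.weights.sum(axis=1)
    with open(node_path, "w") as fh:
        for i in range(atlas.n_nodes):
            x, y, z = atlas.centroids[i]
            color = 1 if i in rich else 2
            fh.write(f"{x:.3f}\t{y:.3f}\t{z:.3f}\t{color}\t{strength[i]:.6g}\t{atlas.labels[i]}\n")
    np.savetxt(edge_path, network.weights, fmt="%.10g", delimiter="\t")
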