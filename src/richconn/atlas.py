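"""Node atlas: region labels, hemispheres, centroids (mm) and volumes.

The atlas plays two roles: it names the network nodes, and its per-node
volumes form the denominator of the edge-weight formula
``w_ij = FN_ij * FA_ij / ((vol_i + vol_j) / 2)``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

# The 45 AAL region abbreviations (each present once per hemisphere in the
# 90-node cortical/subcortical parcellation, cerebellum excluded).
AAL90_REGIONS = (
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup", "MTG", "TPOmid",
    "ITG",
)

ATLAS_COLUMNS = ["node_id", "label", "hemisphere", "x", "y", "z", "volume"]


@dataclass(eq=False)
class NodeAtlas:
    """Immutable-by-convention container for the node definition.

    Parameters
    ----------
    labels : array of str, unique node labels.
    hemispheres : array of {"L", "R"}.
    centroids : (N, 3) float array, node centre-of-mass in mm.
    volumes : (N,) strictly positive float array (voxel counts).
    name : short atlas identifier written into matrix headers.
    """

    labels: np.ndarray
    hemispheres: np.ndarray
    centroids: np.ndarray
    volumes: np.ndarray
    name: str = "synthetic"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.hemispheres = np.asarray(self.hemispheres, dtype=object)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        n = len(self.labels)
        if n < 2:
            raise ValueError("an atlas needs at least 2 nodes")
        if len(set(self.labels.tolist())) != n:
            raise ValueError("atlas labels must be unique")
        if self.centroids.shape != (n, 3):
            raise ValueError("centroids must have shape (n_nodes, 3)")
        if self.volumes.shape != (n,) or np.any(self.volumes <= 0):
            raise ValueError("volumes must be strictly positive, one per node")
        if not set(self.hemispheres.tolist()) <= {"L", "R"}:
            raise ValueError("hemisphere labels must be 'L' or 'R'")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def node_ids(self) -> np.ndarray:
        """1-based node indices."""
        return np.arange(1, self.n_nodes + 1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.centroids[:, 0],
                "y": self.centroids[:, 1],
                "z": self.centroids[:, 2],
                "volume": self.volumes,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, name: str = "synthetic") -> "NodeAtlas":
        df = df.sort_values("node_id")
        return cls(
            labels=df["label"].to_numpy(dtype=object),
            hemispheres=df["hemisphere"].to_numpy(dtype=object),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
            volumes=df["volume"].to_numpy(dtype=float),
            name=name,
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, name: str = "synthetic") -> "NodeAtlas":
        return cls.from_dataframe(pd.read_csv(path), name=name)


def region_labels(n_nodes: int) -> list[str]:
    """Unique node labels with hemispheres alternating L/R.

    For 90 nodes the AAL-90 abbreviations are used (odd index = left);
    any other size gets generic ``Rkkk`` labels.
    """
    labels = []
    for i in range(n_nodes):
        hemi = "L" if i % 2 == 0 else "R"
        if n_nodes == 90:
            base = AAL90_REGIONS[i // 2]
        else:
            base = f"R{i // 2 + 1:03d}"
        labels.append(f"{base}.{hemi}")
    return labels
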