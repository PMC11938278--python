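"""Distance-cutoff spatial graphs with RBF edge features.

The location model connects any two nodes closer than 6 A; the thermo model
uses an 8 A cutoff and drops intra-protein (atom-atom) edges. The boundary
is strict (< cutoff). Edges are stored once as unordered pairs and expanded
to both directions for message passing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .constants import N_RBF

__all__ = ["SpatialGraph", "rbf_expand", "build_graph"]


def rbf_expand(value, n_centers: int = N_RBF, lo: float = 0.0,
               hi: float = 1.0) -> np.ndarray:
    """Gaussian radial-basis expansion of a scalar (or array of scalars).

    Centers are evenly spaced on [lo, hi]; the Gaussian width equals the
    center spacing, so a value sitting exactly on center k activates
    component k at its maximum of 1.
    """
    if not lo < hi:
        raise ValueError("rbf_expand requires lo < hi")
    value = np.asarray(value, dtype=np.float64)
    if np.any(~np.isfinite(value)):
        raise ValueError("rbf_expand received NaN/inf input")
    centers = np.linspace(lo, hi, n_centers)
    width = centers[1] - centers[0]
    return np.exp(-((value[..., None] - centers) ** 2) / width ** 2)


@dataclass
class SpatialGraph:
    node_coords: np.ndarray                 # (N, 3)
    node_kind: np.ndarray                   # (N,) 0 = protein atom, 1 = water
    edges: np.ndarray                       # (E, 2) unordered pairs, i < j
    edge_features: np.ndarray               # (E, 32) RBF of edge length
    node_features: np.ndarray | None = field(default=None)  # (N, 92)
    cutoff: float = 6.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def directed_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """(src, dst) index arrays with every edge in both directions."""
        if len(self.edges) == 0:
            e = np.zeros(0, dtype=np.intp)
            return e, e.copy()
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        return src.astype(np.intp), dst.astype(np.intp)


def build_graph(coords: np.ndarray, cutoff: float,
                node_kind: np.ndarray | None = None,
                node_features: np.ndarray | None = None,
                exclude_pairs: str | None = None) -> SpatialGraph:
    """Connect all node pairs strictly closer than ``cutoff`` Angstrom.

    ``exclude_pairs="atom-atom"`` drops intra-protein edges (both endpoints
    of kind 0), the convention of the thermodynamics graph. Pair search uses
    a KD-tree; the result equals brute-force O(N^2) enumeration.
    """
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 1:
        raise ValueError("coords must be a non-empty (N, 3) array")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if node_kind is None:
        node_kind = np.zeros(len(coords), dtype=np.intp)
    node_kind = np.asarray(node_kind, dtype=np.intp)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) > 0:
        # query_pairs uses <= r; the published convention is strict <.
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    if exclude_pairs == "atom-atom" and len(pairs) > 0:
        keep = ~((node_kind[pairs[:, 0]] == 0) & (node_kind[pairs[:, 1]] == 0))
        pairs = pairs[keep]
    elif exclude_pairs not in (None, "atom-atom"):
        raise ValueError(f"unknown pair-exclusion class: {exclude_pairs}")
    pairs = pairs[np.lexsort((pairs[:, 1], pairs[:, 0]))] if len(pairs) else \
        np.zeros((0, 2), dtype=np.intp)
    if len(pairs) > 0:
        lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]],
                                 axis=1)
        edge_feats = rbf_expand(lengths, lo=0.0, hi=cutoff)
    else:
        edge_feats = np.zeros((0, N_RBF))
    return SpatialGraph(node_coords=coords, node_kind=node_kind,
                        edges=pairs, edge_features=edge_feats,
                        node_features=node_features, cutoff=cutoff)
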