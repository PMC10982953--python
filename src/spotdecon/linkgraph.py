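"""Mutual-nearest-neighbor link graph over cell-type and spot nodes.

Two sub-graphs are built in the latent space with Euclidean distances:
spot–spot and cell-type–spot. For each spot the k nearest spots and k
nearest cell types are candidates (all cell types if fewer than k
exist); for each cell type the k nearest spots are candidates. An edge
is retained only when both endpoints appear in each other's candidate
list; cell-type–cell-type edges are never considered. The two sub-graphs
are merged and distances become weights through

    w_ij = 1 − d_ij / max(d),

where max(d) is taken over the retained edges of the merged graph, so
weights span [0, 1] and only the single farthest edge gets weight 0.
Because mutual-NN filtering precedes the weighting, an isolated outlier
cannot distort existing edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np
from scipy import sparse
from scipy.spatial.distance import cdist

from .coembed import LatentEmbedding

__all__ = ["LinkGraph", "knn_candidates", "build_link_graph"]


@dataclass
class LinkGraph:
    """Symmetric weighted adjacency over the m + n nodes.

    ``A`` holds weights in [0, 1] with a zero diagonal and no
    type–type edges; ``distances`` maps each retained undirected edge
    (i, j), i < j, to its latent Euclidean distance.
    """

    A: np.ndarray
    distances: Dict[Tuple[int, int], float]
    node_roles: np.ndarray
    k: int

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.distances)

    def to_sparse(self) -> sparse.csr_matrix:
        return sparse.csr_matrix(self.A)

    def edge_list(self):
        """(node_i, node_j, weight, distance) rows, i < j."""
        return [(i, j, self.A[i, j], d)
                for (i, j), d in sorted(self.distances.items())]


def _topk(order_source: np.ndarray, dist_row: np.ndarray,
          k: int) -> np.ndarray:
    """Indices of the k smallest distances among ``order_source``
    candidates; ties broken by node index (stable sort)."""
    cand = order_source[np.lexsort((order_source, dist_row[order_source]))]
    return cand[:k]


def knn_candidates(Z: LatentEmbedding, k: int = 20):
    """Role-aware candidate lists with Euclidean latent distances.

    Returns ``(candidates, D)`` where ``candidates[i]`` is a dict with
    keys ``"spot"`` and (for spots) ``"celltype"`` holding index arrays,
    and ``D`` is the full pairwise distance matrix.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_nodes = Z.Z.shape[0]
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    D = cdist(Z.Z, Z.Z)
    roles = np.asarray(Z.node_roles)
    type_idx = np.where(roles == "celltype")[0]
    spot_idx = np.where(roles == "spot")[0]
    candidates: List[dict] = [None] * n_nodes
    for i in type_idx:
        candidates[i] = {"spot": _topk(spot_idx, D[i], k)}
    for i in spot_idx:
        others = spot_idx[spot_idx != i]
        entry = {"spot": _topk(others, D[i], k)}
        # all cell types when m < k ("the spot will connect to all
        # cell types"); otherwise the k nearest
        if len(type_idx) <= k:
            entry["celltype"] = type_idx.copy()
        else:
            entry["celltype"] = _topk(type_idx, D[i], k)
        candidates[i] = entry
    return candidates, D


def build_link_graph(Z: LatentEmbedding, k: int = 20,
                     max_distance_scope: str = "edges") -> LinkGraph:
    """Merge the mutual-NN spot–spot and type–spot sub-graphs and weight
    edges by normalized distance.

    ``max_distance_scope``: ``"edges"`` (default) normalizes by the
    maximum distance among retained edges; ``"global"`` by the maximum
    pairwise distance among all nodes.
    """
    roles = np.asarray(Z.node_roles)
    type_idx = np.where(roles == "celltype")[0]
    spot_idx = np.where(roles == "spot")[0]
    if len(type_idx) < 1 or len(spot_idx) < 1:
        raise ValueError("need at least one cell type and one spot node")
    candidates, D = knn_candidates(Z, k)

    edges: Dict[Tuple[int, int], float] = {}
    cand_sets = [{role: set(v) for role, v in c.items()}
                 for c in candidates]
    # spot–spot sub-graph
    for i in spot_idx:
        for j in candidates[i]["spot"]:
            if i < j and i in cand_sets[j]["spot"]:
                edges[(i, j)] = D[i, j]
    # cell-type–spot sub-graph
    for t in type_idx:
        for s in candidates[t]["spot"]:
            if t in cand_sets[s]["celltype"]:
                key = (min(t, s), max(t, s))
                edges[key] = D[t, s]

    n_nodes = D.shape[0]
    A = np.zeros((n_nodes, n_nodes))
    if not edges:
        import warnings

        warnings.warn("link graph has zero edges", stacklevel=2)
        return LinkGraph(A, edges, roles, k)

    if max_distance_scope == "global":
        dmax = float(D.max())
    else:
        dmax = max(edges.values())
    if dmax == 0:  # all retained edges coincide in latent space
        dmax = 1.0
        weights = {e: 1.0 for e in edges}
    else:
        weights = {e: 1.0 - d / dmax for e, d in edges.items()}
    for (i, j), w in weights.items():
        A[i, j] = A[j, i] = w
    return LinkGraph(A, edges, roles, k)
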