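"""Shared graph containers and efficiency primitives.

Graphs are stored as dense symmetric adjacency matrices (small node counts:
parcellated brain networks), with the sparsification scheme, wiring cost rho
and global cost efficiency J = Eg - rho recorded alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

__all__ = [
    "FilteredGraph",
    "EconomicCurve",
    "binary_distances",
    "binary_global_efficiency",
    "binary_local_efficiency",
    "edge_list",
]


@dataclass
class FilteredGraph:
    """Sparse undirected graph produced by an edge-filtering scheme.

    ``adj`` holds the surviving edges with their (pre weight-scheme) input
    weights; absent edges are 0.  ``cost`` is the scheme's own rho (edge
    density for threshold/planar schemes, retained-weight fraction for the
    orthogonal-tree schemes) and ``gce`` the J = Eg - rho at that cost.
    """

    adj: np.ndarray
    scheme: str = ""
    labels: list[str] = field(default_factory=list)
    weight_scheme: str = "weighted"
    cost: float = float("nan")
    gce: float = float("nan")
    connected: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.adj = np.asarray(self.adj, dtype=float)
        n = self.adj.shape[0]
        if self.adj.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not np.allclose(self.adj, self.adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adj) != 0):
            raise ValueError("self-loops are not allowed")
        if not self.labels:
            self.labels = [f"n{i}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adj.shape[0]

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adj, 1)))

    @property
    def density(self) -> float:
        n = self.n_nodes
        return self.n_edges / (n * (n - 1) / 2) if n > 1 else 0.0

    def binarized(self) -> np.ndarray:
        return (self.adj > 0).astype(float)


@dataclass
class EconomicCurve:
    """Samples of a cost-efficiency sweep: (rho, Eg, J) with the argmax."""

    rho: np.ndarray
    eg: np.ndarray
    j: np.ndarray
    argmax: int
    objective: str = "gce"
    j_ext: np.ndarray | None = None  # ECO's (Eg + Eloc)/rho when applicable

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=float)
        self.eg = np.asarray(self.eg, dtype=float)
        self.j = np.asarray(self.j, dtype=float)
        if np.any(np.diff(self.rho) <= 0):
            raise ValueError("rho samples must be strictly increasing")


def binary_distances(adj: np.ndarray) -> np.ndarray:
    """Hop-count distance matrix of a binary/binarized adjacency."""
    a = (np.asarray(adj) > 0)
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def binary_global_efficiency(adj: np.ndarray, d: np.ndarray | None = None) -> float:
    """Mean of 1/d over distinct node pairs; disconnected pairs count 0."""
    n = adj.shape[0]
    if n < 2:
        return 0.0
    if d is None:
        d = binary_distances(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def binary_local_efficiency_node(adj: np.ndarray, i: int) -> float:
    """Global efficiency of the subgraph induced on node i's neighbours."""
    nbrs = np.flatnonzero(adj[i] > 0)
    if nbrs.size < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)]
    return binary_global_efficiency(sub)


def binary_local_efficiency(adj: np.ndarray) -> float:
    """Mean nodal local efficiency of a binarized adjacency."""
    n = adj.shape[0]
    if n == 0:
        return 0.0
    return float(np.mean([binary_local_efficiency_node(adj, i) for i in range(n)]))


def edge_list(adj: np.ndarray) -> list[tuple[int, int, float]]:
    """Edges (i < j, weight) sorted by weight descending then node pair.

    This is the tie-break order used by every filtering scheme.
    """
    iu, ju = np.triu_indices(adj.shape[0], k=1)
    w = adj[iu, ju]
    keep = w > 0
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, -w))
    return [(int(iu[k]), int(ju[k]), float(w[k])) for k in order]
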