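"""Graph-theory metric suite for filtered brain networks.

Seven global metrics — integration: global efficiency Eg, characteristic
path length Lp, pseudo diameter D; segregation: clustering coefficient Cp,
local efficiency Eloc, modularity Q, transitivity Tr — and ten nodal
metrics: Lp_i, E_nodal_i, E_local_i, Cp_i, PageRank Pc_i, degree/strength
Dc_i, eigenvector Ec_i, resolvent (Katz) Rc_i, subgraph Sc_i and betweenness
Bc_i centralities.

Weighted path lengths use the edge length 1/w (strong correlation = short
distance), recorded per run via :class:`DistanceConvention`.  Disconnected
pairs contribute 0 to efficiency-style metrics and are excluded from path
averages with a ``disconnected`` flag.  Weighted clustering uses the Onnela
geometric-mean form.  Q comes from seeded Louvain, best of 10 restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.linalg import expm
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from sklearn.base import BaseEstimator, TransformerMixin

from .graphs import FilteredGraph

GLOBAL_METRICS = ("Eg", "Lp", "D", "Cp", "Eloc", "Q", "Tr")
NODAL_METRICS = ("Lp", "E_nodal", "E_local", "Cp", "Pc", "Dc", "Ec", "Rc", "Sc", "Bc")


@dataclass(frozen=True)
class DistanceConvention:
    """Edge-length rule for shortest paths: ``reciprocal`` (1/w) or ``unit``."""

    rule: str = "reciprocal"

    def __post_init__(self):
        if self.rule not in ("reciprocal", "unit"):
            raise ValueError("rule must be 'reciprocal' or 'unit'")


@dataclass
class GlobalMetricVector:
    eg: float
    lp: float
    d: float
    cp: float
    eloc: float
    q: float
    tr: float
    flags: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, float]:
        return {"Eg": self.eg, "Lp": self.lp, "D": self.d, "Cp": self.cp,
                "Eloc": self.eloc, "Q": self.q, "Tr": self.tr}


def _as_graph(G) -> FilteredGraph:
    if isinstance(G, FilteredGraph):
        return G
    return FilteredGraph(adj=np.asarray(G, dtype=float))


def _is_binary(adj: np.ndarray) -> bool:
    return bool(np.all((adj == 0) | (adj == 1)))


def _distances(adj: np.ndarray, convention: DistanceConvention) -> np.ndarray:
    if convention.rule == "unit" or _is_binary(adj):
        return shortest_path(csr_matrix(adj > 0), method="D", unweighted=True,
                             directed=False)
    lengths = np.zeros_like(adj)
    nz = adj > 0
    lengths[nz] = 1.0 / adj[nz]
    return shortest_path(csr_matrix(lengths), method="D", directed=False)


def _inv_distances(d: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv


def _nx_graph(adj: np.ndarray) -> nx.Graph:
    G = nx.Graph()
    n = adj.shape[0]
    G.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(adj, 1))
    for i, j in zip(iu, ju):
        G.add_edge(int(i), int(j), weight=float(adj[i, j]),
                   length=float(1.0 / adj[i, j]))
    return G


def _local_efficiency(adj: np.ndarray, i: int, convention: DistanceConvention) -> float:
    nbrs = np.flatnonzero(adj[i] > 0)
    k = nbrs.size
    if k < 2:
        return 0.0
    sub = adj[np.ix_(nbrs, nbrs)]
    inv = _inv_distances(_distances(sub, convention))
    return float(inv.sum() / (k * (k - 1)))


def modularity(G, seed: int = 0, n_restarts: int = 10):
    """Newman weighted modularity of the best seeded-Louvain partition.

    Runs Louvain ``n_restarts`` times with consecutive seeds and returns the
    (Q, partition) of the highest-Q run; deterministic given ``seed``.
    """
    G = _as_graph(G)
    if G.n_edges == 0:
        return 0.0, [set(range(G.n_nodes))]
    H = _nx_graph(G.adj)
    best_q, best_part = -np.inf, None
    for t in range(n_restarts):
        part = nx.community.louvain_communities(H, weight="weight", seed=seed + t)
        q = nx.community.modularity(H, part, weight="weight")
        if q > best_q:
            best_q, best_part = q, part
    return float(best_q), best_part


def global_metrics(G, convention: DistanceConvention = DistanceConvention(),
                   seed: int = 0) -> GlobalMetricVector:
    """The seven global integration/segregation metrics of a graph."""
    G = _as_graph(G)
    n = G.n_nodes
    flags: list[str] = []
    if G.n_edges == 0:
        return GlobalMetricVector(0, 0, 0, 0, 0, 0, 0, flags=["degenerate_empty"])
    adj = G.adj
    d = _distances(adj, convention)
    inv = _inv_distances(d)
    eg = float(inv.sum() / (n * (n - 1)))
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.all() and np.any(~finite & off):
        flags.append("disconnected")
    lp = float(d[finite].mean()) if finite.any() else 0.0
    dmax = float(d[finite].max()) if finite.any() else 0.0  # exact for n <= 200
    if n > 200:
        dmax = _double_sweep_diameter(adj, convention)
    H = _nx_graph(adj)
    if _is_binary(adj):
        cp = float(nx.average_clustering(H))
    else:
        cp = float(nx.average_clustering(H, weight="weight"))
    eloc = float(np.mean([_local_efficiency(adj, i, convention) for i in range(n)]))
    tr = float(nx.transitivity(H))
    q, _ = modularity(G, seed=seed)
    return GlobalMetricVector(eg=eg, lp=lp, d=dmax, cp=cp, eloc=eloc, q=q, tr=tr,
                              flags=flags)


def _double_sweep_diameter(adj: np.ndarray, convention: DistanceConvention) -> float:
    """Double-sweep lower bound on the diameter (used above 200 nodes)."""
    d0 = _distances(adj, convention)[0]
    d0[~np.isfinite(d0)] = -1
    far = int(np.argmax(d0))
    d1 = _distances(adj, convention)[far]
    d1 = d1[np.isfinite(d1)]
    return float(d1.max()) if d1.size else 0.0


def nodal_metrics(G, convention: DistanceConvention = DistanceConvention(),
                  katz_alpha_factor: float = 0.9) -> pd.DataFrame:
    """Ten nodal metrics, one row per node.

    PageRank uses damping 0.85 and sums to 1; resolvent centrality solves
    (I - alpha A) x = 1 with alpha = ``katz_alpha_factor`` / lambda_max;
    subgraph centrality is diag(e^A); betweenness is unnormalized
    shortest-path betweenness (pair counts).  Path-based entries of isolated
    nodes are 0.
    """
    G = _as_graph(G)
    n = G.n_nodes
    adj = G.adj
    d = _distances(adj, convention)
    inv = _inv_distances(d)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    lp_i = np.array([d[i][finite[i]].mean() if finite[i].any() else 0.0
                     for i in range(n)])
    e_nodal = inv.sum(axis=1) / max(n - 1, 1)
    e_local = np.array([_local_efficiency(adj, i, convention) for i in range(n)])
    H = _nx_graph(adj)
    binary = _is_binary(adj)
    cp_i = nx.clustering(H) if binary else nx.clustering(H, weight="weight")
    cp_i = np.array([cp_i[i] for i in range(n)])
    if G.n_edges:
        pr = nx.pagerank(H, alpha=0.85, weight=None if binary else "weight")
    else:
        pr = {i: 1.0 / n for i in range(n)}
    pc = np.array([pr[i] for i in range(n)])
    dc = adj.sum(axis=1)
    evals, evecs = np.linalg.eigh(adj)
    ec = np.abs(evecs[:, -1])
    ec /= np.linalg.norm(ec) or 1.0
    lam = evals[-1]
    if lam > 0:
        alpha = katz_alpha_factor / lam
        rc = np.linalg.solve(np.eye(n) - alpha * adj, np.ones(n))
    else:
        rc = np.ones(n)
    sc = np.diag(expm(adj)).copy()
    bc_d = nx.betweenness_centrality(H, normalized=False,
                                     weight=None if binary else "length")
    bc = np.array([bc_d[i] for i in range(n)])
    return pd.DataFrame(
        {"Lp": lp_i, "E_nodal": e_nodal, "E_local": e_local, "Cp": cp_i,
         "Pc": pc, "Dc": dc, "Ec": ec, "Rc": rc, "Sc": sc, "Bc": bc},
        index=list(G.labels),
    )


class GraphMetricExtractor(BaseEstimator, TransformerMixin):
    """Estimator computing a vector of global metrics from a FilteredGraph."""

    def __init__(self, metrics: tuple[str, ...] = GLOBAL_METRICS,
                 distance: str = "reciprocal", seed: int = 0):
        self.metrics = metrics
        self.distance = distance
        self.seed = seed

    def fit(self, X, y=None):
        unknown = set(self.metrics) - set(GLOBAL_METRICS)
        if unknown:
            raise ValueError(f"unknown metrics {sorted(unknown)}")
        self.convention_ = DistanceConvention(self.distance)
        return self

    def transform(self, X) -> np.ndarray:
        self.fit(X)
        vec = global_metrics(X, self.convention_, seed=self.seed).as_dict()
        return np.array([vec[m] for m in self.metrics])
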