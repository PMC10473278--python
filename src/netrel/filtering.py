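"""Edge filtering: sparsify a dense weight matrix into a brain graph.

Twelve schemes in two families:

threshold-based
    ABS_05 (keep correlations r > 0.5), PROP_10 / PROP_20 (strongest 10% /
    20% of edges), DEG_5 / DEG_15 (strongest K*N/2 edges for mean degree K),
    GCE (sweep edge-weight-ordered prefixes, keep the prefix maximizing
    global cost efficiency J(rho) = Eg(rho) - rho), ECO (same sweep, keep the
    prefix maximizing (Eg + Eloc)/rho; the resulting graphs are sparse with
    mean degree near 3).

topology-based
    MST (maximum-weight spanning tree: N-1 edges, connected, acyclic),
    OMST (union of successive edge-disjoint MSTs, stopped at the round count
    maximizing J with rho = retained-weight fraction), PMFG (greedy maximal
    planar graph, 3(N-2) edges), TMFG (triangulated maximally filtered graph:
    greedy tetrahedron/triangle construction, 3(N-2) edges, planar and
    chordal), and OTMFG (union of successive edge-disjoint TMFGs with the
    OMST-style J-argmax stopping rule).

Every scheme is deterministic: candidate edges are ordered by weight
descending, then lexicographic (i, j) node pair.  Sweep efficiencies are
computed on binarized prefix graphs.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import networkx as nx
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import WeightMatrix
from .graphs import (
    EconomicCurve,
    FilteredGraph,
    binary_distances,
    binary_global_efficiency,
    binary_local_efficiency_node,
    edge_list,
)

THRESHOLD_SCHEMES = ("ABS_05", "PROP_10", "PROP_20", "DEG_5", "DEG_15", "GCE", "ECO")
TOPOLOGY_SCHEMES = ("MST", "OMST", "PMFG", "TMFG", "OTMFG")
ALL_SCHEMES = THRESHOLD_SCHEMES + TOPOLOGY_SCHEMES


def _as_weight_matrix(W) -> WeightMatrix:
    if isinstance(W, WeightMatrix):
        return W
    return WeightMatrix(w=np.asarray(W, dtype=float))


def _graph_from_edges(W: WeightMatrix, edges, scheme: str, cost: float | None = None,
                      flags: list[str] | None = None) -> FilteredGraph:
    n = W.n_nodes
    adj = np.zeros((n, n))
    for i, j, w in edges:
        adj[i, j] = adj[j, i] = w
    g = FilteredGraph(adj=adj, scheme=scheme, labels=list(W.labels), flags=flags or [])
    g.cost = g.density if cost is None else cost
    g.gce = binary_global_efficiency(g.binarized()) - g.cost
    g.connected = _is_connected(adj)
    return g


def _is_connected(adj: np.ndarray) -> bool:
    if adj.shape[0] <= 1:
        return True
    d = binary_distances(adj)
    return bool(np.all(np.isfinite(d)))


# ---------------------------------------------------------------- threshold

def filter_threshold(W, scheme: str) -> FilteredGraph:
    """ABS_05, PROP_10, PROP_20, DEG_5 or DEG_15 thresholding.

    ABS keeps edges whose *source correlation* exceeds 0.5 (the threshold is
    defined on r, before any positivity transform); PROP_p keeps the
    round(p * N(N-1)/2) strongest edges; DEG_K keeps the round(K * N / 2)
    strongest (mean degree K).  Ties are broken by weight descending then
    node pair.
    """
    W = _as_weight_matrix(W)
    n = W.n_nodes
    edges = edge_list(W.w)
    flags: list[str] = []
    if scheme == "ABS_05":
        if W.source_r is None:
            warnings.warn("no source correlations recorded; ABS_05 thresholds the weights")
            kept = [(i, j, w) for i, j, w in edges if w > 0.5]
        else:
            kept = [(i, j, w) for i, j, w in edges if W.source_r[i, j] > 0.5]
    elif scheme.startswith("PROP_") or scheme.startswith("DEG_"):
        if scheme.startswith("PROP_"):
            p = float(scheme.split("_")[1]) / 100.0
            k = int(np.floor(p * n * (n - 1) / 2 + 0.5))
        else:
            K = float(scheme.split("_")[1])
            k = int(np.floor(K * n / 2 + 0.5))
        if k > len(edges):
            raise ValueError(f"{scheme} needs {k} edges but only {len(edges)} are available")
        ws = [w for _, _, w in edges]
        if k and len(set(ws)) == 1 and len(ws) > k:
            warnings.warn(f"{scheme}: all weights equal; deterministic tie-broken subset kept")
            flags.append("tied_weights")
        kept = edges[:k]
    else:
        raise ValueError(f"unknown threshold scheme {scheme!r}")
    return _graph_from_edges(W, kept, scheme, flags=flags)


def _prefix_sweep(W: WeightMatrix, objective: str):
    """Add edges in tie-break order; evaluate the objective at each prefix.

    objective "gce": J = Eg - rho, bounded above by 1 - rho, so the sweep may
    stop once best >= 1 - rho_next.  objective "eco": J_ext = (Eg + Eloc)/rho,
    bounded by 2/rho.  Both bounds are exact (Eg, Eloc <= 1), so early
    stopping never changes the argmax.
    """
    n = W.n_nodes
    m_total = n * (n - 1) // 2
    edges = edge_list(W.w)
    adj = np.zeros((n, n))
    eloc = np.zeros(n)
    rhos, egs, js, jexts = [], [], [], []
    best, best_m = -np.inf, 0
    for m, (i, j, w) in enumerate(edges, start=1):
        adj[i, j] = adj[j, i] = w
        rho = m / m_total
        eg = binary_global_efficiency(adj)
        if objective == "eco":
            touched = {i, j} | set(np.flatnonzero((adj[i] > 0) & (adj[j] > 0)))
            for v in touched:
                eloc[v] = binary_local_efficiency_node(adj, v)
            val = (eg + eloc.mean()) / rho
            jexts.append(val)
        else:
            val = eg - rho
        rhos.append(rho)
        egs.append(eg)
        js.append(eg - rho)
        if val > best:
            best, best_m = val, m
        if m < len(edges):
            bound = (1.0 - (m + 1) / m_total) if objective == "gce" else 2.0 * m_total / (m + 1)
            if best >= bound:
                break
    curve = EconomicCurve(
        rho=np.array(rhos), eg=np.array(egs), j=np.array(js),
        argmax=best_m - 1, objective=objective,
        j_ext=np.array(jexts) if objective == "eco" else None,
    )
    return edges[:best_m], curve


def filter_gce(W) -> tuple[FilteredGraph, EconomicCurve]:
    """Global-cost-efficiency optimum over weight-ordered edge prefixes."""
    W = _as_weight_matrix(W)
    if W.n_nodes < 2:
        raise ValueError("GCE needs at least 2 nodes")
    kept, curve = _prefix_sweep(W, "gce")
    return _graph_from_edges(W, kept, "GCE"), curve


def filter_eco(W) -> tuple[FilteredGraph, EconomicCurve]:
    """Overall efficiency-cost optimum (Eg + Eloc)/rho over edge prefixes."""
    W = _as_weight_matrix(W)
    if W.n_nodes < 4:
        raise ValueError("ECO needs at least 4 nodes")
    kept, curve = _prefix_sweep(W, "eco")
    if curve.argmax == 0:
        warnings.warn("ECO argmax at minimum density (single edge)")
    return _graph_from_edges(W, kept, "ECO"), curve


# ----------------------------------------------------------------- topology

class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _kruskal_max(n: int, edges) -> list[tuple[int, int, float]]:
    """Maximum-weight spanning tree/forest via Kruskal on pre-sorted edges."""
    uf = _UnionFind(n)
    tree = []
    for i, j, w in edges:
        if uf.union(i, j):
            tree.append((i, j, w))
            if len(tree) == n - 1:
                break
    return tree


def filter_mst(W) -> FilteredGraph:
    """Maximum-weight spanning tree (N-1 edges, acyclic, connected).

    Equivalent to the minimum spanning tree on distances 1/w.  A disconnected
    input yields a spanning forest flagged ``disconnected_input``.
    """
    W = _as_weight_matrix(W)
    tree = _kruskal_max(W.n_nodes, edge_list(W.w))
    flags = [] if len(tree) == W.n_nodes - 1 else ["disconnected_input"]
    return _graph_from_edges(W, tree, "MST", flags=flags)


def filter_omst(W) -> tuple[FilteredGraph, EconomicCurve]:
    """Orthogonal MSTs: union of edge-disjoint successive MSTs.

    Round n extracts the maximum spanning tree of the edges not yet selected;
    after aggregating n rounds, J = Eg - rho with rho the selected-weight
    fraction of total weight.  The aggregation maximizing J is returned.
    Iteration stops when the remaining support no longer spans the graph.
    """
    W = _as_weight_matrix(W)
    n = W.n_nodes
    total_weight = W.w[np.triu_indices(n, 1)].sum()
    if total_weight <= 0:
        raise ValueError("OMST needs positive total weight")
    selected: list[tuple[int, int, float]] = []
    used = set()
    rounds: list[list[tuple[int, int, float]]] = []
    rhos, egs, js = [], [], []
    adj = np.zeros((n, n))
    wsum = 0.0
    while True:
        remaining = [(i, j, w) for i, j, w in edge_list(W.w) if (i, j) not in used]
        tree = _kruskal_max(n, remaining)
        if len(tree) < n - 1:
            break
        rounds.append(tree)
        for i, j, w in tree:
            used.add((i, j))
            adj[i, j] = adj[j, i] = 1.0
            wsum += w
        selected.extend(tree)
        rho = wsum / total_weight
        eg = binary_global_efficiency(adj)
        rhos.append(rho)
        egs.append(eg)
        js.append(eg - rho)
        if rho >= 1.0:
            break
    if not rounds:
        raise ValueError("input graph is disconnected; no MST round completed")
    best = int(np.argmax(js))
    kept = [e for r in rounds[: best + 1] for e in r]
    curve = EconomicCurve(rho=np.array(rhos), eg=np.array(egs), j=np.array(js),
                          argmax=best, objective="omst")
    g = _graph_from_edges(W, kept, "OMST", cost=rhos[best])
    return g, curve


def filter_pmfg(W, max_edges: int | None = None) -> FilteredGraph:
    """Planar maximally filtered graph: greedy insertion under planarity.

    Edges are tried strongest-first and kept iff the graph stays planar
    (combinatorial test); construction stops at 3(N-2) edges.
    """
    W = _as_weight_matrix(W)
    n = W.n_nodes
    if n < 3:
        raise ValueError("PMFG needs at least 3 nodes")
    limit = 3 * (n - 2) if max_edges is None else max_edges
    G = nx.Graph()
    G.add_nodes_from(range(n))
    kept = []
    for i, j, w in edge_list(W.w):
        if len(kept) >= limit:
            break
        G.add_edge(i, j)
        if nx.check_planarity(G, counterexample=False)[0]:
            kept.append((i, j, w))
        else:
            G.remove_edge(i, j)
    return _graph_from_edges(W, kept, "PMFG")


def _seed_clique(w: np.ndarray, barred: np.ndarray) -> tuple[int, ...] | None:
    """Max-total-weight 4-clique whose 6 edges are all unbarred.

    Exhaustive (vectorised) for N <= 120; greedy extension of the best
    unbarred edge above that.  Ties resolve to the lexicographically
    smallest vertex tuple.
    """
    n = w.shape[0]
    if n <= 120:
        combos = np.array(list(itertools.combinations(range(n), 4)))
        pair_ix = list(itertools.combinations(range(4), 2))
        total = np.zeros(len(combos))
        ok = np.ones(len(combos), dtype=bool)
        for a, b in pair_ix:
            total += w[combos[:, a], combos[:, b]]
            ok &= ~barred[combos[:, a], combos[:, b]]
        if not ok.any():
            return None
        total[~ok] = -np.inf
        return tuple(int(v) for v in combos[int(np.argmax(total))])
    # greedy: best unbarred edge, then twice the vertex with max gain
    wmask = np.where(barred, -np.inf, w)
    np.fill_diagonal(wmask, -np.inf)
    i, j = np.unravel_index(np.argmax(wmask), wmask.shape)
    if not np.isfinite(wmask[i, j]):
        return None
    clique = [int(min(i, j)), int(max(i, j))]
    for _ in range(2):
        gains = np.full(n, -np.inf)
        for v in range(n):
            if v in clique:
                continue
            if any(barred[v, u] for u in clique):
                continue
            gains[v] = sum(w[v, u] for u in clique)
        v = int(np.argmax(gains))
        if not np.isfinite(gains[v]):
            return None
        clique.append(v)
    return tuple(sorted(clique))


def _tmfg_round(w: np.ndarray, barred: np.ndarray):
    """One TMFG construction avoiding barred edges; None if infeasible.

    Seeds the maximal-total-weight tetrahedron, then repeatedly inserts the
    vertex/triangular-face pair with the highest summed weight, splitting
    that face in three.  Ties break to the lowest vertex index, then the
    earliest face in the current face list.
    """
    n = w.shape[0]
    seed = _seed_clique(w, barred)
    if seed is None:
        return None
    a, b, c, d = seed
    edges = [(min(x, y), max(x, y)) for x, y in itertools.combinations(seed, 2)]
    faces = [(a, b, c), (a, b, d), (a, c, d), (b, c, d)]
    remaining = sorted(set(range(n)) - set(seed))
    while remaining:
        best_gain, best_v, best_f = -np.inf, None, None
        for v in remaining:
            wv, bv = w[v], barred[v]
            for fi, (x, y, z) in enumerate(faces):
                if bv[x] or bv[y] or bv[z]:
                    continue
                gain = wv[x] + wv[y] + wv[z]
                if gain > best_gain:
                    best_gain, best_v, best_f = gain, v, fi
        if best_v is None:
            return None
        x, y, z = faces.pop(best_f)
        v = best_v
        for u in (x, y, z):
            edges.append((min(v, u), max(v, u)))
        faces.extend([(v, x, y), (v, x, z), (v, y, z)])
        remaining.remove(v)
    return edges


def filter_tmfg(W) -> FilteredGraph:
    """Triangulated maximally filtered graph: 3(N-2) edges, planar, chordal."""
    W = _as_weight_matrix(W)
    if W.n_nodes < 4:
        raise ValueError("TMFG needs at least 4 nodes")
    barred = np.zeros_like(W.w, dtype=bool)
    edges = _tmfg_round(W.w, barred)
    if edges is None:
        raise ValueError("TMFG construction infeasible")
    kept = [(i, j, W.w[i, j]) for i, j in edges]
    return _graph_from_edges(W, kept, "TMFG")


def filter_otmfg(W) -> tuple[FilteredGraph, EconomicCurve]:
    """Orthogonal TMFGs: edge-disjoint TMFG rounds, OMST-style J-argmax.

    Round m runs TMFG with all previously selected edges barred; after
    aggregating m rounds, J = Eg - rho with rho the selected-weight fraction.
    Iteration stops when no edge-disjoint TMFG remains.
    """
    W = _as_weight_matrix(W)
    n = W.n_nodes
    if n < 4:
        raise ValueError("OTMFG needs at least 4 nodes")
    total_weight = W.w[np.triu_indices(n, 1)].sum()
    if total_weight <= 0:
        raise ValueError("OTMFG needs positive total weight")
    barred = np.zeros_like(W.w, dtype=bool)
    rounds = []
    rhos, egs, js = [], [], []
    adj = np.zeros((n, n))
    wsum = 0.0
    while True:
        edges = _tmfg_round(W.w, barred)
        if edges is None:
            break
        rounds.append(edges)
        for i, j in edges:
            barred[i, j] = barred[j, i] = True
            adj[i, j] = adj[j, i] = 1.0
            wsum += W.w[i, j]
        rho = wsum / total_weight
        eg = binary_global_efficiency(adj)
        rhos.append(rho)
        egs.append(eg)
        js.append(eg - rho)
        if rho >= 1.0:
            break
    if not rounds:
        raise ValueError("no TMFG round completed")
    best = int(np.argmax(js))
    kept = [(i, j, W.w[i, j]) for r in rounds[: best + 1] for i, j in r]
    curve = EconomicCurve(rho=np.array(rhos), eg=np.array(egs), j=np.array(js),
                          argmax=best, objective="otmfg")
    g = _graph_from_edges(W, kept, "OTMFG", cost=rhos[best])
    return g, curve


# ------------------------------------------------------------------ general

def filter_graph(W, scheme: str) -> FilteredGraph:
    """Dispatch a weight matrix through any of the 12 schemes by name."""
    if scheme in ("ABS_05", "PROP_10", "PROP_20", "DEG_5", "DEG_15"):
        return filter_threshold(W, scheme)
    if scheme == "GCE":
        return filter_gce(W)[0]
    if scheme == "ECO":
        return filter_eco(W)[0]
    if scheme == "MST":
        return filter_mst(W)
    if scheme == "OMST":
        return filter_omst(W)[0]
    if scheme == "PMFG":
        return filter_pmfg(W)
    if scheme == "TMFG":
        return filter_tmfg(W)
    if scheme == "OTMFG":
        return filter_otmfg(W)[0]
    raise ValueError(f"unknown edge-filtering scheme {scheme!r}")


def economic_curve_point(G: FilteredGraph, W) -> tuple[float, float]:
    """(rho, J) of a filtered graph in the cost-efficiency plane.

    rho is edge density except for OMST/OTMFG where it is the retained-weight
    fraction (matching those schemes' objectives); J = Eg - rho with Eg on
    the binarized graph.
    """
    W = _as_weight_matrix(W)
    if G.scheme in ("OMST", "OTMFG"):
        total = W.w[np.triu_indices(W.n_nodes, 1)].sum()
        rho = G.adj[np.triu_indices(G.n_nodes, 1)].sum() / total
    else:
        rho = G.density
    eg = binary_global_efficiency(G.binarized())
    return rho, eg - rho


class EdgeFilter(BaseEstimator, TransformerMixin):
    """Estimator wrapper turning a WeightMatrix into a FilteredGraph."""

    def __init__(self, scheme: str = "OMST"):
        self.scheme = scheme

    def fit(self, X, y=None):
        if self.scheme not in ALL_SCHEMES:
            raise ValueError(f"scheme must be one of {ALL_SCHEMES}")
        return self

    def transform(self, X) -> FilteredGraph:
        self.fit(X)
        return filter_graph(X, self.scheme)
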