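"""Connectivity matrices from nodal time series and positivity transforms.

An N x N Pearson correlation matrix R = (r_ij) is estimated from band-limited
node time series, Fisher z-transformed (z = atanh r), and mapped to a
nonnegative weight matrix W = (w_ij) by one of four transforms:

    pos:  w = (z + |z|) / 2          (half-rectification)
    abs:  w = |z|
    exp:  w = e**z
    div:  w = 2 / sqrt(2 (1 - r))    (constant over the correlation distance)

pos/abs/exp act on z; div acts on r.  The ``div`` constant is configurable
(``div_constant=1`` gives the plain reciprocal correlation distance).  The
diagonal is excluded everywhere: no self-loops.

Edge-weight schemes (applied after edge filtering): ``binary`` sets every
surviving edge to 1, ``weighted`` keeps the weights, ``normalized`` divides
by the maximum surviving weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

TRANSFORMS = ("pos", "abs", "exp", "div")
WEIGHT_SCHEMES = ("binary", "weighted", "normalized")

_CLIP = 1.0 - 1e-7


@dataclass
class CorrelationMatrix:
    """Symmetric unit-diagonal Pearson correlation matrix with node labels."""

    r: np.ndarray
    labels: list[str] = field(default_factory=list)
    band: str = ""

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if not self.labels:
            self.labels = [f"n{i}" for i in range(n)]


@dataclass
class WeightMatrix:
    """Symmetric nonnegative zero-diagonal weight matrix.

    ``source_r`` keeps the correlation matrix the weights were derived from;
    the ABS edge-filtering scheme thresholds on it.
    """

    w: np.ndarray
    transform: str = ""
    labels: list[str] = field(default_factory=list)
    source_r: np.ndarray | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        n = self.w.shape[0]
        if self.w.shape != (n, n):
            raise ValueError("weight matrix must be square")
        if np.any(self.w < 0):
            raise ValueError("weights must be nonnegative")
        if not np.allclose(self.w, self.w.T):
            raise ValueError("weight matrix must be symmetric")
        if not self.labels:
            self.labels = [f"n{i}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]


def pearson_matrix(ts: np.ndarray, labels: list[str] | None = None, band: str = "") -> CorrelationMatrix:
    """Pearson correlation of a node x time matrix.

    Zero-variance nodes are flagged with a warning and their correlations set
    to 0 (diagonal stays 1).
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("need a node x time matrix with >= 3 time points")
    sd = ts.std(axis=1)
    dead = sd <= 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} zero-variance node(s); correlations set to 0")
        ts = ts.copy()
        ts[dead] += np.nan  # corrcoef -> nan, replaced below
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(ts)
    r = np.nan_to_num(r, nan=0.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r=r, labels=labels or [], band=band)


def fisher_z(r):
    """Fisher z-transform atanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("|r| >= 1 encountered; clipped before atanh")
        r = np.clip(r, -_CLIP, _CLIP)
    return np.arctanh(r)


def transform_weights(R: CorrelationMatrix | np.ndarray, method: str, div_constant: float = 2.0) -> WeightMatrix:
    """Map a correlation matrix to nonnegative weights (diagonal zeroed)."""
    if method not in TRANSFORMS:
        raise ValueError(f"method must be one of {TRANSFORMS}")
    if isinstance(R, np.ndarray):
        R = CorrelationMatrix(r=R)
    r = R.r.copy()
    off = ~np.eye(r.shape[0], dtype=bool)
    if method == "div":
        rc = np.clip(r, -1.0, _CLIP)
        w = div_constant / np.sqrt(2.0 * (1.0 - rc))
    else:
        z = np.zeros_like(r)
        z[off] = fisher_z(r[off])
        if method == "pos":
            w = np.maximum(z, 0.0)
        elif method == "abs":
            w = np.abs(z)
        else:  # exp
            w = np.exp(z)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w, transform=method, labels=list(R.labels), source_r=R.r)


def apply_weight_scheme(G, scheme: str):
    """Re-weight a filtered graph's surviving edges.

    binary: every surviving edge gets weight 1; weighted: unchanged;
    normalized: weights divided by the maximum surviving weight (so the
    strongest edge becomes 1).  An empty graph under ``normalized`` is
    returned unchanged with a warning.
    """
    from .graphs import FilteredGraph  # local import; graphs has no deps here

    if scheme not in WEIGHT_SCHEMES:
        raise ValueError(f"scheme must be one of {WEIGHT_SCHEMES}")
    adj = G.adj.copy()
    if scheme == "binary":
        adj = (adj > 0).astype(float)
    elif scheme == "normalized":
        mx = adj.max()
        if mx <= 0:
            warnings.warn("empty graph under normalized weighting; returned as-is")
        else:
            adj = adj / mx
    out = FilteredGraph(adj=adj, scheme=G.scheme, labels=list(G.labels),
                        weight_scheme=scheme, cost=G.cost, gce=G.gce,
                        connected=G.connected, flags=list(G.flags))
    return out


class ConnectivityTransformer(BaseEstimator, TransformerMixin):
    """Estimator mapping node x time series to a nonnegative WeightMatrix."""

    def __init__(self, method: str = "pos", div_constant: float = 2.0):
        self.method = method
        self.div_constant = div_constant

    def fit(self, X, y=None):
        if self.method not in TRANSFORMS:
            raise ValueError(f"method must be one of {TRANSFORMS}")
        return self

    def transform(self, X) -> WeightMatrix:
        self.fit(X)
        R = pearson_matrix(np.asarray(X, dtype=float))
        return transform_weights(R, self.method, self.div_constant)
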