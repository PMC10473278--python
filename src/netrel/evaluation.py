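"""Run the analytic grid over a cohort and compare choices statistically.

The grid crosses frequency band x connectivity transform x edge-filtering
scheme x edge-weight scheme x global metric; for each cell the cohort's
scans are reduced to one metric observation per (subject, visit,
measurement), the three-level LMM yields the dependability ICC with its
variability anatomy, and the resulting ICC table is compared across choices
with Friedman rank-sum tests (effect size Kendall's W = chi2 / (n (k - 1))),
pairwise Wilcoxon signed-rank post hocs with Bonferroni correction, and the
descriptive summaries mean ICC and "noap" (number of almost-perfect ICCs,
ICC >= 0.8).

A sample-size helper evaluates the Walter-Eliasziw-Donner approximation for
the minimal number of subjects needed to detect a target ICC.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .bands import bandpass, partition_slow_bands
from .cohort import CohortTimeseries
from .connectivity import apply_weight_scheme, pearson_matrix, transform_weights
from .filtering import filter_graph
from .metrics import GLOBAL_METRICS, DistanceConvention, global_metrics
from .reliability import estimate_icc

__all__ = [
    "GridConfig", "ChoiceTestResult", "run_grid", "summarize_choice",
    "friedman_choice_test", "pairwise_wilcoxon", "power_min_n",
]

FACTOR_COLUMNS = ("node_set", "band", "transform", "filter", "weight_scheme")
NOAP_THRESHOLD = 0.8


@dataclass
class GridConfig:
    """Analytic choices to cross over a cohort."""

    node_set: str = "synthetic"
    bands: list[str] = field(default_factory=lambda: ["slow-4", "slow-5"])
    transforms: list[str] = field(default_factory=lambda: ["pos"])
    filters: list[str] = field(default_factory=lambda: ["OMST", "PROP_10"])
    weight_schemes: list[str] = field(default_factory=lambda: ["normalized"])
    metrics: list[str] = field(default_factory=lambda: list(GLOBAL_METRICS))
    seed: int = 0
    n_boot: int = 200
    distance: str = "reciprocal"
    cache_dir: str | None = None

    def __post_init__(self):
        for name in ("bands", "transforms", "filters", "weight_schemes", "metrics"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be nonempty")

    @property
    def n_cells(self) -> int:
        return (len(self.bands) * len(self.transforms) * len(self.filters)
                * len(self.weight_schemes) * len(self.metrics))


@dataclass
class ChoiceTestResult:
    """Friedman rank-sum comparison of ICC distributions across choices."""

    factor: str
    statistic: float
    df: int
    p_value: float
    kendall_w: float
    n_blocks: int
    dropped_blocks: int = 0
    pairwise: pd.DataFrame | None = None


def _cohort_hash(cohort: CohortTimeseries) -> str:
    h = hashlib.sha1()
    for key in cohort.keys():
        h.update(repr(key).encode())
        h.update(np.ascontiguousarray(cohort[key]).tobytes())
    return h.hexdigest()[:16]


def _cell_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % (2**31))


def run_grid(config: GridConfig, cohort: CohortTimeseries) -> pd.DataFrame:
    """Compute the ICC table over the full analytic grid.

    For every scan: band-filter -> Pearson correlation -> positivity
    transform -> edge filter -> weight scheme -> global metrics; metric
    observations are then pooled per cell into a measurement table and the
    ICC estimated (closed-form balanced fit + cluster bootstrap).  Cells are
    cached by content hash when ``config.cache_dir`` is set, making reruns
    and resumption cheap; per-cell bootstrap seeds derive from the master
    seed, so the table is deterministic.
    """
    scan_keys = cohort.keys()
    tr = cohort.tr
    n_volumes = cohort[scan_keys[0]].shape[1]
    available = {b.name for b in partition_slow_bands(tr, n_volumes, include_empirical=True)}
    unknown = set(config.bands) - available
    if unknown:
        raise ValueError(f"bands {sorted(unknown)} unavailable at tr={tr}, T={n_volumes}")
    band_objs = {b.name: b for b in partition_slow_bands(tr, n_volumes, include_empirical=True)}
    convention = DistanceConvention(config.distance)
    cache_dir = Path(config.cache_dir) if config.cache_dir else None
    if cache_dir:
        cache_dir.mkdir(parents=True, exist_ok=True)
    data_hash = _cohort_hash(cohort) if cache_dir else ""

    # metric observations per (band, transform, filter, scheme): scan -> vector
    rows = []
    cells = list(itertools.product(config.bands, config.transforms,
                                   config.filters, config.weight_schemes))
    for cell_idx, (band, transform, scheme, wscheme) in enumerate(cells):
        descriptor = {"node_set": config.node_set, "band": band,
                      "transform": transform, "filter": scheme,
                      "weight_scheme": wscheme, "metrics": config.metrics,
                      "n_boot": config.n_boot, "seed": config.seed,
                      "distance": config.distance, "data": data_hash}
        cache_file = None
        if cache_dir:
            key = hashlib.sha1(json.dumps(descriptor, sort_keys=True).encode()).hexdigest()
            cache_file = cache_dir / f"{key}.json"
            if cache_file.exists():
                rows.extend(json.loads(cache_file.read_text()))
                continue
        cell_rows = []
        try:
            records = []
            for (k, j, i) in scan_keys:
                ts = bandpass(cohort[(k, j, i)], band_objs[band], tr)
                R = pearson_matrix(ts, labels=list(cohort.labels), band=band)
                W = transform_weights(R, transform)
                G = filter_graph(W, scheme)
                G = apply_weight_scheme(G, wscheme)
                vec = global_metrics(G, convention, seed=config.seed).as_dict()
                records.append(((k, j, i), vec))
            for m_idx, metric in enumerate(config.metrics):
                table = pd.DataFrame(
                    [{"subject": k, "visit": j, "measurement": i,
                      "value": vec[metric]} for (k, j, i), vec in records])
                res = estimate_icc(
                    table, n_boot=config.n_boot,
                    seed=_cell_seed(config.seed, cell_idx * len(config.metrics) + m_idx))
                cell_rows.append({
                    "node_set": config.node_set, "band": band,
                    "transform": transform, "filter": scheme,
                    "weight_scheme": wscheme, "metric": metric,
                    "icc": res.icc, "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "vb": res.vb, "vw": res.vw, "level": res.level,
                })
        except Exception as exc:  # cell-level failures are isolated
            warnings.warn(f"grid cell {descriptor} failed: {exc}")
            continue
        if cache_file:
            cache_file.write_text(json.dumps(cell_rows))
        rows.extend(cell_rows)
    return pd.DataFrame(rows)


def summarize_choice(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Mean ICC (general reliability) and noap count (potential reliability,
    ICC >= 0.8) per level of a factor."""
    if factor not in FACTOR_COLUMNS:
        raise ValueError(f"factor must be one of {FACTOR_COLUMNS}")
    out = (table.groupby(factor)["icc"]
           .agg(mean_icc="mean", noap=lambda s: int((s >= NOAP_THRESHOLD).sum()),
                n="size")
           .reset_index())
    return out


def _block_matrix(table: pd.DataFrame, factor: str):
    """Pivot ICCs to blocks x levels; blocks are full crossings of the other
    factors (plus metric); incomplete blocks are dropped."""
    others = [c for c in (*FACTOR_COLUMNS, "metric") if c != factor and c in table.columns]
    levels = sorted(table[factor].unique())
    piv = table.pivot_table(index=others, columns=factor, values="icc", aggfunc="mean")
    complete = piv.dropna()
    return complete[levels].to_numpy(), levels, len(piv) - len(complete)


def friedman_choice_test(table: pd.DataFrame, factor: str) -> ChoiceTestResult:
    """Friedman rank-sum test on within-block mid-ranks.

    chi2 = 12/(n k (k+1)) sum_j R_j^2 - 3 n (k+1), df = k - 1, and Kendall's
    W = chi2 / (n (k - 1)).  Requires >= 2 complete blocks and >= 2 levels.
    """
    X, levels, dropped = _block_matrix(table, factor)
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError("Friedman test needs >= 2 complete blocks and >= 2 levels")
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    rj = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(rj**2) - 3.0 * n * (k + 1)
    chi2 = max(chi2, 0.0)
    df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    w = chi2 / (n * (k - 1))
    return ChoiceTestResult(factor=factor, statistic=float(chi2), df=df, p_value=p,
                            kendall_w=float(w), n_blocks=n, dropped_blocks=dropped)


def signed_rank_statistic(d: np.ndarray) -> tuple[float, float, int]:
    """(V, z, n) for paired differences: V = sum of positive mid-ranks of |d|
    after dropping zeros; z uses the normal approximation with tie
    correction."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return float("nan"), float("nan"), 0
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    z = (v - mu) / math.sqrt(var) if var > 0 else float("nan")
    return v, z, n


def pairwise_wilcoxon(table: pd.DataFrame, factor: str) -> pd.DataFrame:
    """Post-hoc pairwise Wilcoxon signed-rank tests between factor levels.

    Pairs are matched by block; V is the positive-rank sum, the effect size
    r = |z| / sqrt(n); p-values are two-sided (exact for < 10 nonzero pairs,
    normal approximation with tie/zero corrections otherwise) and
    Bonferroni-multiplied by the number of level pairs, capped at 1.
    """
    X, levels, _ = _block_matrix(table, factor)
    pairs = list(itertools.combinations(range(len(levels)), 2))
    n_pairs = len(pairs)
    out = []
    for a, b in pairs:
        d = X[:, a] - X[:, b]
        v, z, n_nz = signed_rank_statistic(d)
        if n_nz == 0:
            out.append({"choice_a": levels[a], "choice_b": levels[b],
                        "V": float("nan"), "effect_size_r": 0.0,
                        "p_raw": 1.0, "p_bonferroni": 1.0, "n": 0,
                        "note": "all-zero differences; test refused"})
            continue
        method = "exact" if n_nz < 10 else "approx"
        try:
            p = float(stats.wilcoxon(X[:, a], X[:, b], zero_method="wilcox",
                                     alternative="two-sided", method=method).pvalue)
        except ValueError:  # exact method refuses ties; fall back
            p = float(stats.wilcoxon(X[:, a], X[:, b], zero_method="wilcox",
                                     alternative="two-sided", method="approx").pvalue)
        r = abs(z) / math.sqrt(n_nz) if np.isfinite(z) else 0.0
        out.append({"choice_a": levels[a], "choice_b": levels[b], "V": v,
                    "effect_size_r": r, "p_raw": p,
                    "p_bonferroni": min(1.0, p * n_pairs), "n": n_nz, "note": ""})
    return pd.DataFrame(out)


def power_min_n(rho_null: float, rho_alt: float, k_repeats: int,
                alpha: float = 0.05, power: float = 0.8) -> int:
    """Minimal subjects to detect ICC rho_alt against rho_null.

    Walter-Eliasziw-Donner approximation with k repeated observations per
    subject and a one-sided test:

        n = 1 + 2 k (z_{1-a} + z_{1-b})^2 / ((k - 1) (ln C0)^2),
        C0 = (1 + k r0/(1-r0)) / (1 + k r1/(1-r1)),

    rounded to the nearest integer.  With rho_null = 0, rho_alt = 0.2,
    k = 4, alpha = 0.05, power = 0.8 this gives 35.
    """
    if not (0 <= rho_null < rho_alt < 1):
        raise ValueError("need 0 <= rho_null < rho_alt < 1")
    if k_repeats < 2:
        raise ValueError("need k_repeats >= 2")
    za = stats.norm.ppf(1 - alpha)
    zb = stats.norm.ppf(power)
    c0 = (1 + k_repeats * rho_null / (1 - rho_null)) / \
         (1 + k_repeats * rho_alt / (1 - rho_alt))
    n = 1 + 2 * k_repeats * (za + zb) ** 2 / ((k_repeats - 1) * math.log(c0) ** 2)
    return int(math.floor(n + 0.5))
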