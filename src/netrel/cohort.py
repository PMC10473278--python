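"""Synthetic test-retest cohorts with known ground-truth variance structure.

Two generators mirror a test-retest design of P subjects x M visits x n
measurement occasions per visit (defaults emulate a fast-TR retest cohort:
41 subjects, 2 visits, 2 measurements per visit, 1,200 volumes at
TR = 0.72 s):

* :func:`simulate_lmm_metrics` draws metric observations directly from the
  three-level generative model (fixed mean + subject, visit-within-subject
  and residual Gaussian effects, optional covariate slopes) — the ground
  truth for ICC parameter-recovery studies.

* :func:`simulate_cohort_timeseries` draws band-limited stationary Gaussian
  node time series whose correlation structure carries the same three-level
  hierarchy: a modular group correlation matrix, a subject-specific
  perturbation (scale ``subject_dev_scale``, the between-subject knob) and a
  scan-specific perturbation (``scan_dev_scale``, within-subject).
  Perturbations are symmetric Gaussian matrices with zero diagonal;
  perturbed matrices are repaired to valid correlations by eigenvalue
  clipping and re-normalization.  Spectral content is shaped by inverse-DFT
  masking of white noise, giving exact band-limited power.

Covariates emulate the retest cohort's ranges: age ~ U(22, 35) years, sex ~
Bernoulli(0.5), inter-visit interval ~ U(18, 328) days; covariate effects
default to zero.

The perturbation model is a stand-in for the (unknown) generative structure
of real between-subject connectome differences; see the methods note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import FrequencyBand, partition_slow_bands, _band_mask

__all__ = [
    "CohortDesign", "GroundTruthVariances", "StructureParams", "CohortTimeseries",
    "simulate_lmm_metrics", "make_group_covariance", "simulate_cohort_timeseries",
]

DEFAULT_BAND_POWER = {"slow-5": 1.0, "slow-4": 1.0}


@dataclass(frozen=True)
class CohortDesign:
    """Shape of a test-retest cohort."""

    n_subjects: int = 41
    n_visits: int = 2
    n_measurements_per_visit: int = 2
    n_nodes: int = 60
    n_volumes: int = 1200
    tr: float = 0.72
    seed: int = 0

    def __post_init__(self):
        for name in ("n_subjects", "n_visits", "n_measurements_per_visit",
                     "n_nodes", "n_volumes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass(frozen=True)
class GroundTruthVariances:
    """Parameters of the three-level generative model for a metric."""

    fixed_mean: float = 0.0
    sigma2_subject: float = 1.0
    sigma2_visit: float = 0.25
    sigma2_residual: float = 0.25
    age_effect: float = 0.0
    sex_effect: float = 0.0
    interval_effect: float = 0.0

    def __post_init__(self):
        for name in ("sigma2_subject", "sigma2_visit", "sigma2_residual"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative")

    @property
    def icc(self) -> float:
        denom = self.sigma2_subject + self.sigma2_residual
        return self.sigma2_subject / denom if denom > 0 else float("nan")


@dataclass(frozen=True)
class StructureParams:
    """Connectivity structure driving the time-series generator."""

    n_modules: int = 4
    within_module_r: float = 0.5
    between_module_r: float = 0.1
    subject_dev_scale: float = 0.2   # between-subject perturbation (eta_b)
    scan_dev_scale: float = 0.1      # within-subject perturbation (eta_w)

    def __post_init__(self):
        for name in ("within_module_r", "between_module_r"):
            r = getattr(self, name)
            if not -1 < r < 1:
                raise ValueError(f"{name} must be in (-1, 1)")
        if self.subject_dev_scale < 0 or self.scan_dev_scale < 0:
            raise ValueError("perturbation scales must be nonnegative")


@dataclass
class CohortTimeseries:
    """Per-scan node x time matrices plus design metadata and covariates."""

    scans: dict[tuple[int, int, int], np.ndarray]
    tr: float
    covariates: pd.DataFrame
    design: CohortDesign | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        shapes = {m.shape for m in self.scans.values()}
        if len(shapes) > 1:
            raise ValueError("all scan matrices must share one shape")
        for m in self.scans.values():
            if not np.all(np.isfinite(m)):
                raise ValueError("scan matrices must be finite")
        if not self.labels and self.scans:
            n = next(iter(self.scans.values())).shape[0]
            self.labels = [f"n{i}" for i in range(n)]

    def keys(self):
        return sorted(self.scans)

    def __getitem__(self, key):
        return self.scans[key]


def _draw_covariates(rng: np.random.Generator, n_subjects: int) -> pd.DataFrame:
    return pd.DataFrame({
        "subject": np.arange(n_subjects),
        "age": rng.uniform(22.0, 35.0, n_subjects),
        "sex": rng.integers(0, 2, n_subjects).astype(float),
        "interval": rng.uniform(18.0, 328.0, n_subjects),
    })


def simulate_lmm_metrics(design: CohortDesign, truth: GroundTruthVariances,
                         seed: int | None = None) -> pd.DataFrame:
    """Draw one metric table from the three-level generative model.

    Returns a long-format table with one row per (subject, visit,
    measurement) and covariate columns; deterministic given the seed
    (``design.seed`` unless overridden).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    P, M, n = design.n_subjects, design.n_visits, design.n_measurements_per_visit
    cov = _draw_covariates(rng, P)
    p0 = rng.normal(0.0, np.sqrt(truth.sigma2_subject), P)
    v0 = rng.normal(0.0, np.sqrt(truth.sigma2_visit), (P, M))
    e = rng.normal(0.0, np.sqrt(truth.sigma2_residual), (P, M, n))
    shift = (truth.fixed_mean
             + truth.age_effect * cov["age"].to_numpy()
             + truth.sex_effect * cov["sex"].to_numpy()
             + truth.interval_effect * cov["interval"].to_numpy())
    value = shift[:, None, None] + p0[:, None, None] + v0[:, :, None] + e
    k, j, i = np.meshgrid(np.arange(P), np.arange(M), np.arange(n), indexing="ij")
    out = pd.DataFrame({
        "subject": k.ravel(), "visit": j.ravel(), "measurement": i.ravel(),
        "value": value.ravel(),
    })
    return out.merge(cov, on="subject", how="left")


def _repair_correlation(c: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """PSD repair: clip eigenvalues at 0, re-normalize to unit diagonal."""
    c = (c + c.T) / 2.0
    vals, vecs = np.linalg.eigh(c)
    if vals[0] >= -tol:
        out = c
    else:
        out = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    d = np.sqrt(np.clip(np.diag(out), tol, None))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    out = np.clip((out + out.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(out, 1.0)
    return out


def make_group_covariance(n_nodes: int, structure: StructureParams) -> np.ndarray:
    """Block-modular group correlation matrix, PSD-repaired, unit diagonal."""
    if structure.n_modules > n_nodes:
        raise ValueError("more modules than nodes")
    blocks = np.array_split(np.arange(n_nodes), structure.n_modules)
    c = np.full((n_nodes, n_nodes), structure.between_module_r)
    for b in blocks:
        c[np.ix_(b, b)] = structure.within_module_r
    np.fill_diagonal(c, 1.0)
    c = _repair_correlation(c)
    min_eig = float(np.linalg.eigvalsh(c)[0])
    if min_eig < -1e-8:
        raise ValueError(f"covariance not PSD after repair (min eigenvalue {min_eig:.3e})")
    return c


def _symmetric_perturbation(rng: np.random.Generator, n: int) -> np.ndarray:
    s = rng.normal(0.0, 1.0, (n, n))
    s = (s + s.T) / np.sqrt(2.0)
    np.fill_diagonal(s, 0.0)
    return s


def _sqrt_psd(c: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(c)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def _band_amplitude(bands: list[FrequencyBand], band_power: dict[str, float],
                    n_volumes: int, tr: float) -> np.ndarray:
    amp = np.zeros(n_volumes // 2 + 1)
    by_name = {b.name: b for b in bands}
    for name, power in band_power.items():
        if power < 0:
            raise ValueError("band power weights must be nonnegative")
        if name not in by_name:
            raise ValueError(f"unknown band {name!r}; available: {sorted(by_name)}")
        mask = _band_mask(by_name[name], n_volumes, tr)
        if not mask.any():
            warnings.warn(f"band {name} has no DFT bins at T={n_volumes}, tr={tr}")
        amp[mask] = np.sqrt(power)
    return amp


def simulate_cohort_timeseries(design: CohortDesign,
                               structure: StructureParams = StructureParams(),
                               band_power: dict[str, float] | None = None,
                               seed: int | None = None) -> CohortTimeseries:
    """Generate a full test-retest cohort of band-limited node time series.

    Per subject: Sigma_subject = repair(Sigma_group + eta_b * S_k); per scan:
    Sigma_scan = repair(Sigma_subject + eta_w * S_ijk), with S symmetric
    Gaussian perturbations.  Each scan is stationary Gaussian noise with
    covariance Sigma_scan, spectrally masked to the requested bands.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    band_power = dict(band_power or DEFAULT_BAND_POWER)
    N, T, tr = design.n_nodes, design.n_volumes, design.tr
    bands = partition_slow_bands(tr, T, include_empirical=True)
    amp = _band_amplitude(bands, band_power, T, tr)
    lowest = min(b.f_low for b in bands if band_power.get(b.name, 0) > 0)
    if lowest < 1.0 / (T * tr):
        warnings.warn("scan too short for one cycle of the lowest requested band")
    sigma_group = make_group_covariance(N, structure)
    cov = _draw_covariates(rng, design.n_subjects)
    scans: dict[tuple[int, int, int], np.ndarray] = {}
    for k in range(design.n_subjects):
        sigma_subj = _repair_correlation(
            sigma_group + structure.subject_dev_scale * _symmetric_perturbation(rng, N))
        for j in range(design.n_visits):
            for i in range(design.n_measurements_per_visit):
                sigma_scan = _repair_correlation(
                    sigma_subj + structure.scan_dev_scale * _symmetric_perturbation(rng, N))
                z = rng.standard_normal((N, T))
                y = _sqrt_psd(sigma_scan) @ z
                spec = np.fft.rfft(y, axis=1) * amp
                y = np.fft.irfft(spec, n=T, axis=1)
                sd = y.std(axis=1, keepdims=True)
                sd[sd == 0] = 1.0
                scans[(k, j, i)] = y / sd
    return CohortTimeseries(scans=scans, tr=tr, covariates=cov, design=design)
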