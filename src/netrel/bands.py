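"""Log-linear slow-frequency-band partition and DFT band-pass filtering.

Spontaneous-activity oscillations are organised into frequency classes whose
boundaries are evenly spaced on a natural-log axis, so any two neighbouring
band edges have the constant ratio e.  Given a repetition time (TR) and scan
length, the analyzable range (DC exclusive, Nyquist inclusive) is partitioned
into the slow bands slow-6 ... slow-1, with theoretical boundaries at
``e**(-k-0.5)`` Hz snapped to the discrete-Fourier-transform frequency grid
``i / (T * TR)``.  The band containing the Nyquist frequency is truncated at
Nyquist and marked with a trailing ``-`` (e.g. ``slow-1-`` at TR = 0.72 s);
bands entirely above Nyquist are dropped.  The floor of slow-6 is ``e**-5``
Hz by convention (configurable).

Filtering is an ideal (brick-wall) DFT mask: a band keeps the bins with
``f_low < f <= f_high``, which makes the bands an exact, orthogonal partition
of the frequency grid and the decomposition perfectly invertible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FrequencyBand",
    "BandDecomposition",
    "theoretical_band",
    "partition_slow_bands",
    "bandpass",
    "decompose",
    "BandDecomposer",
]

#: fixed empirical band used throughout the resting-state literature
SLOW_EMP = (0.01, 0.08)


@dataclass(frozen=True)
class FrequencyBand:
    """A frequency interval ``(f_low, f_high]`` in Hz.

    ``low_bin``/``high_bin`` hold the DFT bin indices when the band has been
    snapped to a grid; they allow exact masking without floating-point
    boundary ambiguity.  ``theoretical_low``/``theoretical_high`` are the
    un-snapped e-power boundaries.
    """

    name: str
    f_low: float
    f_high: float
    theoretical_low: float = float("nan")
    theoretical_high: float = float("nan")
    low_bin: int | None = None
    high_bin: int | None = None

    def __post_init__(self):
        if not (0 <= self.f_low < self.f_high):
            raise ValueError(
                f"invalid band {self.name}: ({self.f_low}, {self.f_high}]"
            )


@dataclass
class BandDecomposition:
    """Additive decomposition of a node x time matrix into band components.

    ``components[name] + residual + dc`` reconstructs the input to floating
    point tolerance; components of distinct bands are orthogonal because the
    DFT masks are disjoint.
    """

    components: dict[str, np.ndarray]
    residual: np.ndarray
    dc: np.ndarray
    bands: list[FrequencyBand] = field(default_factory=list)

    def reconstruct(self) -> np.ndarray:
        out = self.dc + self.residual
        for comp in self.components.values():
            out = out + comp
        return out


def theoretical_band(k: int) -> tuple[float, float]:
    """Un-snapped boundaries of slow-k, ``(e**(-k+0.5), e**(-k+1.5))`` Hz.

    Independent of TR; rounded to 4 decimals (the convention used when the
    boundaries are reported).  ``theoretical_band(1) == (0.6065, 1.6487)``.
    """
    if not 1 <= k <= 6:
        raise ValueError("slow-band index k must be in 1..6")
    return (round(math.exp(-k + 0.5), 4), round(math.exp(-k + 1.5), 4))


def _snap(f_theory: float, n_volumes: int, tr: float) -> int:
    """Nearest DFT bin index for a frequency (half-up on exact ties)."""
    return int(math.floor(f_theory * n_volumes * tr + 0.5))


def partition_slow_bands(
    tr: float,
    n_volumes: int,
    slow6_floor: float = math.exp(-5),
    include_empirical: bool = False,
) -> list[FrequencyBand]:
    """Partition the DFT grid of a scan into the log-linear slow bands.

    Parameters
    ----------
    tr : repetition time in seconds (> 0).
    n_volumes : number of time points (>= 2).
    slow6_floor : lower edge of slow-6 before snapping; ``e**-5`` Hz by
        default, which reproduces the printed 0.0069 Hz at TR = 0.72 s,
        T = 1200.
    include_empirical : append the fixed slow-emp band (0.01-0.08 Hz),
        which overlaps slow-4/slow-5 and is not part of the partition.

    Returns bands ordered slow-6 (lowest) to slow-1 (highest); a band cut by
    the Nyquist frequency is truncated there and suffixed ``-``; bands whose
    lower edge reaches Nyquist are omitted (a notice is warned).
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if n_volumes < 2:
        raise ValueError("n_volumes must be >= 2")
    nyq_bin = n_volumes // 2
    duration = n_volumes * tr
    nyquist = nyq_bin / duration

    bands: list[FrequencyBand] = []
    for k in range(6, 0, -1):
        lo_t = slow6_floor if k == 6 else math.exp(-k + 0.5)
        hi_t = math.exp(-k + 1.5)
        lo_bin = _snap(lo_t, n_volumes, tr)
        hi_bin = _snap(hi_t, n_volumes, tr)
        name = f"slow-{k}"
        if lo_bin >= nyq_bin:
            warnings.warn(
                f"{name} ({lo_t:.4f}-{hi_t:.4f} Hz) above Nyquist "
                f"{nyquist:.4f} Hz; omitted"
            )
            continue
        if hi_bin > nyq_bin:
            hi_bin = nyq_bin
            name += "-"
        if hi_bin <= lo_bin:
            warnings.warn(
                f"{name} ({lo_t:.4f}-{hi_t:.4f} Hz) narrower than one DFT bin "
                f"at resolution {1 / duration:.4f} Hz; omitted"
            )
            continue
        bands.append(
            FrequencyBand(
                name=name,
                f_low=round(lo_bin / duration, 4),
                f_high=round(hi_bin / duration, 4),
                theoretical_low=round(lo_t, 4),
                theoretical_high=round(hi_t, 4),
                low_bin=lo_bin,
                high_bin=hi_bin,
            )
        )
    if include_empirical:
        bands.append(
            FrequencyBand(
                "slow-emp", SLOW_EMP[0], SLOW_EMP[1], SLOW_EMP[0], SLOW_EMP[1]
            )
        )
    return bands


def _band_mask(band: FrequencyBand, n_volumes: int, tr: float) -> np.ndarray:
    """Boolean mask over rfft bins retaining ``f_low < f <= f_high``."""
    n_bins = n_volumes // 2 + 1
    idx = np.arange(n_bins)
    if band.low_bin is not None and band.high_bin is not None:
        return (idx > band.low_bin) & (idx <= band.high_bin)
    freqs = idx / (n_volumes * tr)
    eps = 0.5 / (n_volumes * tr) * 1e-9
    return (freqs > band.f_low + eps) & (freqs <= band.f_high + eps)


def bandpass(ts: np.ndarray, band: FrequencyBand, tr: float) -> np.ndarray:
    """Ideal band-pass filter of a node x time matrix by DFT masking.

    Keeps bins with ``f_low < f <= f_high`` (low-exclusive, so DC never
    survives) and inverse transforms; the operation is linear and the output
    real.
    """
    ts = np.asarray(ts, dtype=float)
    one_d = ts.ndim == 1
    X = np.atleast_2d(ts)
    n = X.shape[1]
    nyquist = 1.0 / (2.0 * tr)
    if band.f_low >= nyquist:
        raise ValueError(f"band {band.name} lies above Nyquist {nyquist:.4f} Hz")
    spec = np.fft.rfft(X, axis=1)
    spec[:, ~_band_mask(band, n, tr)] = 0.0
    out = np.fft.irfft(spec, n=n, axis=1)
    return out[0] if one_d else out


def decompose(ts: np.ndarray, tr: float, bands: list[FrequencyBand] | None = None) -> BandDecomposition:
    """Decompose node x time data into slow-band components + DC + residual.

    The residual collects the grid frequencies below the slow-6 floor
    (and any bins not claimed by a band); summing everything reconstructs
    the input exactly up to floating point error.
    """
    ts = np.asarray(ts, dtype=float)
    X = np.atleast_2d(ts)
    n = X.shape[1]
    if bands is None:
        bands = partition_slow_bands(tr, n)
    spec = np.fft.rfft(X, axis=1)
    claimed = np.zeros(n // 2 + 1, dtype=bool)
    comps: dict[str, np.ndarray] = {}
    for b in bands:
        mask = _band_mask(b, n, tr)
        if np.any(mask & claimed):
            raise ValueError(f"band {b.name} overlaps a previous band")
        claimed |= mask
        s = np.zeros_like(spec)
        s[:, mask] = spec[:, mask]
        comps[b.name] = np.fft.irfft(s, n=n, axis=1)
    dc_spec = np.zeros_like(spec)
    dc_spec[:, 0] = spec[:, 0]
    dc = np.fft.irfft(dc_spec, n=n, axis=1)
    res_mask = ~claimed
    res_mask[0] = False
    s = np.zeros_like(spec)
    s[:, res_mask] = spec[:, res_mask]
    residual = np.fft.irfft(s, n=n, axis=1)
    if ts.ndim == 1:
        comps = {k: v[0] for k, v in comps.items()}
        dc, residual = dc[0], residual[0]
    return BandDecomposition(components=comps, residual=residual, dc=dc, bands=list(bands))


class BandDecomposer(BaseEstimator, TransformerMixin):
    """Transformer that band-pass filters node x time matrices.

    Parameters
    ----------
    tr : repetition time in seconds.
    band : band name to retain (``"slow-4"`` ... ``"slow-1-"``,
        ``"slow-emp"``); the grid is derived from the data length at fit.
    slow6_floor : theoretical lower edge of slow-6 before snapping.
    """

    def __init__(self, tr: float = 0.72, band: str = "slow-4", slow6_floor: float = math.exp(-5)):
        self.tr = tr
        self.band = band
        self.slow6_floor = slow6_floor

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        bands = partition_slow_bands(
            self.tr, X.shape[1], slow6_floor=self.slow6_floor, include_empirical=True
        )
        by_name = {b.name: b for b in bands}
        if self.band not in by_name:
            raise ValueError(
                f"band {self.band!r} not available; choose from {sorted(by_name)}"
            )
        self.bands_ = bands
        self.band_ = by_name[self.band]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return bandpass(X, self.band_, self.tr)
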