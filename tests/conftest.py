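"""Shared fixtures and helpers for the netrel test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from netrel import CohortDesign, GroundTruthVariances, simulate_lmm_metrics
from netrel.connectivity import WeightMatrix, pearson_matrix, transform_weights


def random_weight_matrix(n: int, seed: int, t: int | None = None) -> WeightMatrix:
    """Pearson-correlation-derived positive weight matrix of white noise."""
    rng = np.random.default_rng(seed)
    ts = rng.standard_normal((n, t if t is not None else 4 * n))
    return transform_weights(pearson_matrix(ts), "pos")


def random_dense_matrix(n: int, seed: int) -> WeightMatrix:
    """Strictly positive, all-distinct symmetric weight matrix."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(0.01, 1.0, size=(n, n))
    w = (a + a.T) / 2.0
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w=w)


def balanced_table(P=10, M=2, n=2, icc=0.6, seed=0) -> pd.DataFrame:
    design = CohortDesign(n_subjects=P, n_visits=M, n_measurements_per_visit=n)
    truth = GroundTruthVariances(sigma2_subject=icc, sigma2_visit=0.2,
                                 sigma2_residual=1.0 - icc)
    return simulate_lmm_metrics(design, truth, seed=seed)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
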