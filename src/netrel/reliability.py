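"""Test-retest reliability via a three-level linear mixed model.

A graph metric phi observed for subject k at visit j, measurement occasion i
is modelled as

    phi_ijk = gamma000 + p_0k + v_0jk + e_ijk

with independent Gaussian random effects: subject intercepts p_0k
(variance sigma2_p0), visit-within-subject intercepts v_0jk (sigma2_v0) and
residuals e_ijk (sigma2_e).  Age, sex and inter-visit interval may enter as
fixed-effect covariates.  The dependability intraclass correlation is

    ICC = sigma2_p0 / (sigma2_p0 + sigma2_e)

(the visit variance is excluded from the denominator, exactly as the
dependability form is defined; an inclusive variant is available via
``include_visit_variance``).  Normalized variability "anatomy" uses the full
total: Vb = sigma2_p0 / total, Vw = sigma2_e / total with
total = sigma2_p0 + sigma2_v0 + sigma2_e.

Estimation: REML through statsmodels MixedLM in the general case; for
balanced designs without covariates the closed-form nested-ANOVA method of
moments is used (identical to REML in the interior of the parameter space
for balanced nested designs, and fast enough to drive the cluster
bootstrap).  Negative component estimates are truncated at zero.

Confidence intervals come from a nonparametric cluster bootstrap: subjects
are resampled with replacement keeping each subject's full repeated-measures
block, and the 2.5/97.5 percentiles of the refitted ICCs are reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "LMMFit", "ICCResult", "GradientVector",
    "fit_three_level_lmm", "icc_from_fit", "bootstrap_ci", "classify_icc",
    "variability_anatomy", "reliability_gradient", "estimate_icc",
    "ICCEstimator",
]

REQUIRED_COLUMNS = ("subject", "visit", "measurement", "value")

ICC_LEVELS = (
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


@dataclass
class LMMFit:
    gamma000: float
    sigma2_subject: float
    sigma2_visit: float
    sigma2_residual: float
    slopes: dict[str, float] = field(default_factory=dict)
    method: str = "anova"
    converged: bool = True
    loglik: float = float("nan")
    n_subjects: int = 0


@dataclass
class ICCResult:
    icc: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    level: str | None = None
    vb: float = float("nan")
    vw: float = float("nan")
    fit: LMMFit | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class GradientVector:
    """Reliability gradient between two analytic choices.

    Plotted in the variability plane with x = delta Vw, y = delta Vb; the
    angle theta = atan2(dVb, dVw) and the magnitude is the ICC change.
    Quadrant II (Vb up, Vw down) is the optimal direction; I and III are
    suboptimal; IV (Vb down, Vw up) adverse.
    """

    d_vb: float
    d_vw: float
    theta: float
    magnitude: float
    quadrant: str | None

    @property
    def quality(self) -> str | None:
        return {None: None, "I": "suboptimal", "II": "optimal",
                "III": "suboptimal", "IV": "adverse"}[self.quadrant]


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"measurement table lacks columns {missing}")
    if table["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if not np.all(np.isfinite(table["value"].to_numpy(dtype=float))):
        raise ValueError("metric values must be finite")
    counts = table.groupby("subject").size()
    if (counts >= 2).sum() < 1:
        raise ValueError("need repeated measurements for at least one subject")
    if (counts == 1).any():
        warnings.warn("single-repeat subjects present; they inform only the mean")
    return table


def _is_balanced(table: pd.DataFrame) -> bool:
    cell = table.groupby(["subject", "visit"]).size()
    if cell.nunique() != 1:
        return False
    visits = table.groupby("subject")["visit"].nunique()
    return visits.nunique() == 1 and visits.iloc[0] == table["visit"].nunique()


def _balanced_array(table: pd.DataFrame) -> np.ndarray:
    """(P, M, n) value array of a balanced table, sorted by indices."""
    t = table.sort_values(["subject", "visit", "measurement"])
    P = t["subject"].nunique()
    M = t["visit"].nunique()
    return t["value"].to_numpy(dtype=float).reshape(P, M, -1)


def anova_components(y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Nested-ANOVA method-of-moments variance components.

    ``y`` has shape (..., P, M, n): subjects x visits x measurements, with
    arbitrary leading batch axes (used to vectorise the bootstrap).  Returns
    (sigma2_subject, sigma2_visit, sigma2_residual), truncated at zero.
    """
    y = np.asarray(y, dtype=float)
    P, M, n = y.shape[-3:]
    ybar_jk = y.mean(axis=-1)
    ybar_k = ybar_jk.mean(axis=-1)
    ybar = ybar_k.mean(axis=-1)
    if n > 1:
        sse = ((y - ybar_jk[..., None]) ** 2).sum(axis=(-1, -2, -3))
        mse = sse / (P * M * (n - 1))
    else:
        mse = None
    if M > 1:
        ssv = n * ((ybar_jk - ybar_k[..., None]) ** 2).sum(axis=(-1, -2))
        msv = ssv / (P * (M - 1))
    else:
        msv = None
    ssp = n * M * ((ybar_k - ybar[..., None]) ** 2).sum(axis=-1)
    msp = ssp / (P - 1)
    zeros = np.zeros_like(msp)
    if mse is None and msv is None:
        raise ValueError("need at least two repeats per subject")
    if mse is None:
        # single measurement per visit: visit and residual are confounded;
        # attribute the within-subject mean square to the residual
        se2 = msv
        sv2 = zeros
        sp2 = np.maximum((msp - msv) / M, 0.0)
    elif msv is None:
        se2 = mse
        sv2 = zeros
        sp2 = np.maximum((msp - mse) / n, 0.0)
    else:
        se2 = mse
        sv2 = np.maximum((msv - mse) / n, 0.0)
        sp2 = np.maximum((msp - msv) / (n * M), 0.0)
    return sp2, sv2, se2


def _fit_anova(table: pd.DataFrame) -> LMMFit:
    y = _balanced_array(table)
    sp2, sv2, se2 = anova_components(y)
    return LMMFit(gamma000=float(y.mean()), sigma2_subject=float(sp2),
                  sigma2_visit=float(sv2), sigma2_residual=float(se2),
                  method="anova", converged=True, n_subjects=y.shape[0])


def _fit_reml(table: pd.DataFrame, covariates: list[str] | None) -> LMMFit:
    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = table.copy()
    covariates = list(covariates or [])
    scales = {}
    terms = []
    for c in covariates:
        x = df[c].to_numpy(dtype=float)
        sd = x.std()
        scales[c] = sd if sd > 0 else 1.0
        df[f"_z_{c}"] = (x - x.mean()) / scales[c]
        terms.append(f"_z_{c}")
    formula = "value ~ 1" + "".join(f" + {t}" for t in terms)
    df["visit"] = df["visit"].astype("category")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        md = MixedLM.from_formula(formula, groups="subject", re_formula="1",
                                  vc_formula={"visit": "0 + C(visit)"}, data=df)
        res = md.fit(reml=True)
    slopes = {c: float(res.fe_params[f"_z_{c}"]) / scales[c] for c in covariates}
    return LMMFit(
        gamma000=float(res.fe_params["Intercept"]),
        sigma2_subject=max(float(np.asarray(res.cov_re)[0, 0]), 0.0),
        sigma2_visit=max(float(res.vcomp[0]), 0.0),
        sigma2_residual=max(float(res.scale), 0.0),
        slopes=slopes, method="reml", converged=bool(res.converged),
        loglik=float(res.llf), n_subjects=int(table["subject"].nunique()),
    )


def fit_three_level_lmm(table: pd.DataFrame, covariates: list[str] | None = None,
                        method: str = "auto") -> LMMFit:
    """Estimate the three-level variance decomposition of a metric table.

    ``method="anova"`` (balanced designs, no covariates) uses the closed-form
    nested method of moments; ``"reml"`` uses statsmodels MixedLM with subject
    and visit-within-subject random intercepts; ``"auto"`` picks the former
    whenever it applies.  Variance components are nonnegative by construction.
    """
    table = _validate_table(table)
    if method == "auto":
        method = "anova" if (_is_balanced(table) and not covariates) else "reml"
    if method == "anova":
        if covariates:
            raise ValueError("the closed-form path does not adjust covariates")
        if not _is_balanced(table):
            raise ValueError("the closed-form path requires a balanced design")
        return _fit_anova(table)
    if method == "reml":
        return _fit_reml(table, covariates)
    raise ValueError("method must be 'auto', 'anova' or 'reml'")


def icc_from_fit(fit: LMMFit, include_visit_variance: bool = False) -> ICCResult:
    """Dependability ICC = sigma2_subject / (sigma2_subject + sigma2_residual).

    The visit variance is excluded from the denominator (the printed
    definition); pass ``include_visit_variance=True`` for the variant with
    sigma2_visit in the error term.  The value is clamped to [0, 1).
    """
    if not fit.converged:
        raise ValueError("cannot form an ICC from a non-converged fit")
    denom = fit.sigma2_subject + fit.sigma2_residual
    if include_visit_variance:
        denom += fit.sigma2_visit
    flags = []
    if denom <= 0:
        icc = float("nan")
        flags.append("undefined_zero_variance")
        level = None
    else:
        icc = min(max(fit.sigma2_subject / denom, 0.0), 1.0 - 1e-12)
        level = classify_icc(icc)
    vb, vw = variability_anatomy(fit)
    return ICCResult(icc=icc, level=level, vb=vb, vw=vw, fit=fit, flags=flags)


def classify_icc(icc: float) -> str:
    """Five-level label: slight (0,.2], fair (.2,.4], moderate (.4,.6],
    substantial (.6,.8], almost perfect (.8,1)."""
    if not 0 <= icc <= 1:
        raise ValueError("icc must be in [0, 1]")
    for upper, label in ICC_LEVELS:
        if icc <= upper:
            return label
    return "almost perfect"


def variability_anatomy(fit: LMMFit) -> tuple[float, float]:
    """Normalized (Vb, Vw): subject and residual variance over the total."""
    tot = fit.sigma2_subject + fit.sigma2_visit + fit.sigma2_residual
    if tot <= 0:
        warnings.warn("zero total variance; Vb/Vw undefined")
        return float("nan"), float("nan")
    return fit.sigma2_subject / tot, fit.sigma2_residual / tot


def bootstrap_ci(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                 covariates: list[str] | None = None,
                 include_visit_variance: bool = False) -> tuple[float, float]:
    """Percentile 95% CI for the ICC by subject-level (cluster) bootstrap.

    Subjects are resampled with replacement, keeping each subject's full
    block of repeated measurements; deterministic given ``seed``.  Balanced
    designs without covariates use a fully vectorised closed-form refit; the
    general path refits by REML and the CI is flagged unstable if more than
    20% of replicates fail to converge.
    """
    table = _validate_table(table)
    subjects = np.array(sorted(table["subject"].unique()))
    P = subjects.size
    if P < 5:
        raise ValueError("bootstrap needs at least 5 subjects")
    rng = np.random.default_rng(seed)
    if _is_balanced(table) and not covariates:
        y = _balanced_array(table)
        idx = rng.integers(0, P, size=(n_boot, P))
        sp2, sv2, se2 = anova_components(y[idx])
        denom = sp2 + se2 + (sv2 if include_visit_variance else 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            iccs = np.where(denom > 0, sp2 / np.maximum(denom, 1e-300), np.nan)
    else:
        iccs = np.full(n_boot, np.nan)
        groups = {s: g for s, g in table.groupby("subject")}
        failed = 0
        for b in range(n_boot):
            draw = rng.integers(0, P, size=P)
            parts = []
            for new_id, si in enumerate(draw):
                g = groups[subjects[si]].copy()
                g["subject"] = new_id
                parts.append(g)
            bt = pd.concat(parts, ignore_index=True)
            try:
                fit = fit_three_level_lmm(bt, covariates=covariates)
                if not fit.converged:
                    failed += 1
                    continue
                iccs[b] = icc_from_fit(fit, include_visit_variance).icc
            except Exception:
                failed += 1
        if failed > 0.2 * n_boot:
            warnings.warn(f"{failed}/{n_boot} bootstrap refits failed; CI unstable")
    iccs = iccs[np.isfinite(iccs)]
    if iccs.size == 0:
        return float("nan"), float("nan")
    lo, hi = np.percentile(iccs, [2.5, 97.5])
    return float(lo), float(hi)


def estimate_icc(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0,
                 covariates: list[str] | None = None, method: str = "auto",
                 include_visit_variance: bool = False) -> ICCResult:
    """Fit the LMM, form the ICC, and attach a bootstrap CI."""
    fit = fit_three_level_lmm(table, covariates=covariates, method=method)
    res = icc_from_fit(fit, include_visit_variance)
    if n_boot:
        res.ci_low, res.ci_high = bootstrap_ci(
            table, n_boot=n_boot, seed=seed, covariates=covariates,
            include_visit_variance=include_visit_variance)
    return res


def reliability_gradient(from_result: ICCResult, to_result: ICCResult) -> GradientVector:
    """Vector (dVw, dVb) describing how a pipeline change moves reliability.

    Magnitude is the ICC change; theta = atan2(dVb, dVw).  Quadrants are
    labelled on the (x=dVw, y=dVb) plane; II (dVw < 0, dVb > 0) is optimal,
    I and III suboptimal, IV adverse; a vector on an axis (or zero) carries
    no quadrant.
    """
    d_vb = to_result.vb - from_result.vb
    d_vw = to_result.vw - from_result.vw
    if d_vw > 0 and d_vb > 0:
        quad = "I"
    elif d_vw < 0 and d_vb > 0:
        quad = "II"
    elif d_vw < 0 and d_vb < 0:
        quad = "III"
    elif d_vw > 0 and d_vb < 0:
        quad = "IV"
    else:
        quad = None
    return GradientVector(d_vb=d_vb, d_vw=d_vw, theta=math.atan2(d_vb, d_vw),
                          magnitude=to_result.icc - from_result.icc, quadrant=quad)


class ICCEstimator(BaseEstimator):
    """sklearn-style estimator: fit a measurement table, expose ICC results.

    Fitted attributes: ``components_`` (LMMFit), ``icc_``, ``ci_``,
    ``level_``, ``vb_``, ``vw_``.
    """

    def __init__(self, n_boot: int = 1000, seed: int = 0,
                 covariates: list[str] | None = None, method: str = "auto",
                 include_visit_variance: bool = False):
        self.n_boot = n_boot
        self.seed = seed
        self.covariates = covariates
        self.method = method
        self.include_visit_variance = include_visit_variance

    def fit(self, X: pd.DataFrame, y=None):
        res = estimate_icc(X, n_boot=self.n_boot, seed=self.seed,
                           covariates=self.covariates, method=self.method,
                           include_visit_variance=self.include_visit_variance)
        self.result_ = res
        self.components_ = res.fit
        self.icc_ = res.icc
        self.ci_ = (res.ci_low, res.ci_high)
        self.level_ = res.level
        self.vb_ = res.vb
        self.vw_ = res.vw
        return self
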