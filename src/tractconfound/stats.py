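"""Group comparisons, regression, confounding and influence diagnostics.

Implements the analysis stage: independent t-tests for stroke-control
contrasts, ordinary least squares for the three hypothesis models

    cCRST strength ~ iCorticomotor strength
    6MWD ~ cCRST strength
    6MWD ~ cCRST strength + iCorticomotor strength,

the change-in-estimate rule (confounding is declared when adjustment shrinks
the exposure coefficient by more than 10%), Cook's-distance influence
screening against the median of F(p, n-p), leave-one-out sensitivity refits,
and minimum-detectable-effect calculations from exact noncentral-t power (t
tests) or the Fisher-z approximation with small-sample bias correction
(correlations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "RegressionResult",
    "ConfoundingAssessment",
    "InfluenceReport",
    "GroupComparison",
    "group_compare",
    "fit_linear",
    "assess_confounding",
    "cooks_influence",
    "loo_sensitivity",
    "min_detectable_effect",
]


@dataclass
class RegressionResult:
    """OLS fit with the diagnostics the influence analysis needs."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    resid_se: float
    df_resid: int
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_pvalue: float
    residuals: np.ndarray
    leverages: np.ndarray
    cooks_distances: np.ndarray
    n: int
    n_coef: int
    ids: np.ndarray
    # retained for leave-one-out refits
    design: pd.DataFrame = field(repr=False)
    response: np.ndarray = field(repr=False)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Estimate": self.params,
                "SE": self.bse,
                "t value": self.tvalues,
                "Pr(>|t|)": self.pvalues,
            }
        )


@dataclass
class ConfoundingAssessment:
    """Change-in-estimate verdict for one exposure/covariate pair."""

    unadjusted_coef: float
    adjusted_coef: float
    shrinkage_fraction: float
    threshold: float
    confounded: bool
    unadjusted_fit: RegressionResult = field(repr=False)
    adjusted_fit: RegressionResult = field(repr=False)


@dataclass
class InfluenceReport:
    cooks_distances: pd.Series
    threshold: float
    flagged_ids: list
    loo_tables: dict  # flagged id -> before/after coefficient DataFrame


@dataclass
class GroupComparison:
    difference: float  # stroke mean - control mean
    ci_low: float
    ci_high: float
    p_value: float
    stroke_mean: float
    control_mean: float
    stroke_sd: float
    control_sd: float
    variant: str


def group_compare(
    values: np.ndarray,
    groups: np.ndarray,
    variant: str = "pooled",
    alpha: float = 0.05,
) -> GroupComparison:
    """Stroke-minus-control mean difference with CI and p value.

    ``variant`` is "pooled" (classic independent t-test, equivalent to the
    two-group linear-model contrast) or "welch".  Zero-variance degenerate
    inputs are guarded: identical groups give p = 1; distinct means with zero
    within-group variance give p -> 0 with a collapsed CI.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    stroke = values[groups == "stroke"]
    control = values[groups == "control"]
    if len(stroke) < 2 or len(control) < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = float(stroke.mean() - control.mean())
    s1, s0 = float(stroke.std(ddof=1)), float(control.std(ddof=1))
    if s1 == 0.0 and s0 == 0.0:
        p = 1.0 if diff == 0.0 else 0.0
        return GroupComparison(diff, diff, diff, p, float(stroke.mean()),
                               float(control.mean()), s1, s0, variant)
    usevar = "pooled" if variant == "pooled" else "unequal"
    cm = sm.stats.CompareMeans(
        sm.stats.DescrStatsW(stroke), sm.stats.DescrStatsW(control)
    )
    _, p, _ = cm.ttest_ind(usevar=usevar)
    lo, hi = cm.tconfint_diff(alpha=alpha, usevar=usevar)
    return GroupComparison(diff, float(lo), float(hi), float(p),
                           float(stroke.mean()), float(control.mean()), s1, s0, variant)


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns via the QR pivots' diagonal
        _, r = np.linalg.qr(mat)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-10 * max(diag.max(), 1))[0]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def fit_linear(
    y: np.ndarray | pd.Series,
    X: pd.DataFrame,
    ids: np.ndarray | None = None,
    add_intercept: bool = True,
) -> RegressionResult:
    """Ordinary least squares with intercept, residuals, leverages and
    Cook's distances populated."""
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if add_intercept:
        X = sm.add_constant(X, prepend=True, has_constant="add")
        X = X.rename(columns={"const": "(Intercept)"})
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than coefficients ({k})")
    _check_rank(X)
    if ids is None:
        ids = np.arange(n)
    fit = sm.OLS(y, X).fit()
    infl = fit.get_influence()
    leverages = infl.hat_matrix_diag
    cooks = infl.cooks_distance[0]
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        resid_se=float(np.sqrt(fit.mse_resid)),
        df_resid=int(fit.df_resid),
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        residuals=np.asarray(fit.resid),
        leverages=np.asarray(leverages),
        cooks_distances=np.asarray(cooks),
        n=n,
        n_coef=k,
        ids=np.asarray(ids),
        design=X,
        response=y,
    )


def assess_confounding(
    outcome: np.ndarray,
    exposure: np.ndarray,
    covariate: np.ndarray,
    threshold: float = 0.10,
    ids: np.ndarray | None = None,
    exposure_name: str = "exposure",
    covariate_name: str = "covariate",
) -> ConfoundingAssessment:
    """Change-in-estimate confounding test.

    Fits outcome ~ exposure and outcome ~ exposure + covariate; the shrinkage
    fraction is (|b_unadj| - |b_adj|) / |b_unadj| and confounding is declared
    when it strictly exceeds ``threshold``.  A sign flip with a larger
    adjusted magnitude yields negative shrinkage (reported, never flagged).
    """
    outcome = np.asarray(outcome, dtype=float)
    if len(outcome) < 4:
        raise ValueError("need at least 4 observations")
    X10 = pd.DataFrame({exposure_name: exposure})
    X11 = pd.DataFrame({exposure_name: exposure, covariate_name: covariate})
    m10 = fit_linear(outcome, X10, ids=ids)
    m11 = fit_linear(outcome, X11, ids=ids)
    b_u = float(m10.params[exposure_name])
    b_a = float(m11.params[exposure_name])
    if abs(b_u) < 1e-12:
        raise ValueError("unadjusted coefficient is (numerically) zero; shrinkage undefined")
    shrink = (abs(b_u) - abs(b_a)) / abs(b_u)
    return ConfoundingAssessment(
        unadjusted_coef=b_u,
        adjusted_coef=b_a,
        shrinkage_fraction=float(shrink),
        threshold=threshold,
        confounded=bool(shrink > threshold),
        unadjusted_fit=m10,
        adjusted_fit=m11,
    )


def cooks_influence(fit: RegressionResult) -> InfluenceReport:
    """Flag observations whose Cook's distance exceeds the median of
    F(p, n-p), p counting the intercept, and probe each by leave-one-out."""
    p, n = fit.n_coef, fit.n
    if np.any(fit.leverages >= 1.0 - 1e-12):
        raise ValueError("an observation has leverage 1; Cook's distance undefined")
    threshold = float(sps.f.ppf(0.5, p, n - p))
    d = pd.Series(fit.cooks_distances, index=fit.ids, name="cooks_distance")
    flagged = list(d.index[d > threshold])
    loo = {pid: loo_sensitivity(fit, pid) for pid in flagged}
    return InfluenceReport(
        cooks_distances=d, threshold=threshold, flagged_ids=flagged, loo_tables=loo
    )


def loo_sensitivity(fit: RegressionResult, drop_id) -> pd.DataFrame:
    """Refit without one observation; before/after coefficient table."""
    keep = fit.ids != drop_id
    if keep.all():
        raise ValueError(f"observation {drop_id!r} not present in the fit")
    if keep.sum() <= fit.n_coef:
        raise ValueError("dropping this observation leaves too few rows to refit")
    X = fit.design.loc[keep]
    refit = sm.OLS(fit.response[keep], X).fit()
    return pd.DataFrame(
        {
            "before": fit.params,
            "after": refit.params,
            "change": refit.params - fit.params,
        }
    )


def _t_power(effect: float, df: float, ncp_scale: float, alpha: float) -> float:
    ncp = effect * ncp_scale
    tcrit = sps.t.ppf(1 - alpha / 2, df)
    with np.errstate(all="ignore"):
        upper = sps.nct.sf(tcrit, df, ncp)
        lower = sps.nct.cdf(-tcrit, df, ncp)
    # far tails of the noncentral t underflow to NaN
    if np.isnan(upper):
        upper = 1.0
    if np.isnan(lower):
        lower = 0.0
    return float(upper + lower)


def _corr_power(r: float, n: int, alpha: float) -> float:
    # Fisher z with the r/(2(n-1)) small-sample bias correction
    tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
    rc = np.sqrt(tcrit**2 / (tcrit**2 + n - 2))
    zr = np.arctanh(r) + r / (2 * (n - 1))
    zrc = np.arctanh(rc)
    scale = np.sqrt(n - 3)
    return float(
        sps.norm.cdf((zr - zrc) * scale) + sps.norm.cdf((-zr - zrc) * scale)
    )


def min_detectable_effect(
    test: str, n: int, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Smallest effect size detectable with the requested power.

    ``test`` is "within_t" (one-sample/paired d, n pairs), "between_t"
    (two-sample d, n per group) or "correlation" (Pearson r, total n).  The
    effect is root-found so that exact noncentral-t power (t tests) or the
    bias-corrected Fisher-z power (correlation) equals ``power`` at a
    two-sided ``alpha``.
    """
    if test == "within_t":
        if n < 3:
            raise ValueError("within_t needs n >= 3")
        f = lambda d: _t_power(d, n - 1, np.sqrt(n), alpha) - power
        hi = 20.0
    elif test == "between_t":
        if n < 3:
            raise ValueError("between_t needs n >= 3 per group")
        f = lambda d: _t_power(d, 2 * n - 2, np.sqrt(n / 2.0), alpha) - power
        hi = 20.0
    elif test == "correlation":
        if n < 4:
            raise ValueError("correlation needs n >= 4")
        f = lambda r: _corr_power(r, n, alpha) - power
        hi = 1.0 - 1e-9
    else:
        raise ValueError(f"unknown test family {test!r}")
    if f(hi) < 0:
        raise ValueError(f"requested power {power} unattainable at n = {n}")
    return float(optimize.brentq(f, 1e-9, hi, xtol=1e-10))
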