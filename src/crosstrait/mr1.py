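"""One-sample Mendelian randomization on individual-level cohort data.

The instrument is an unweighted polygenic score (count of exposure-increasing
alleles over the instrument SNVs — external weights cannot be used when the
GWAS and the analysis cohort overlap).  The causal effect is the
covariate-adjusted Wald ratio, algebraically identical to two-stage least
squares with a single instrument.  Subgroup analyses refit within sex, age
band (default <65 / >=65, closed lower bound) and menopause strata; the
nonlinear analysis stratifies on residual exposure (observed exposure minus
the mean-centered genetic contribution), estimates the Wald ratio per
quartile, and tests heterogeneity (Cochran Q) and trend (meta-regression of
stratum estimates on stratum mean exposure).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import Cohort

__all__ = [
    "StratumEstimate",
    "NonlinearResult",
    "WeakInstrumentError",
    "build_prs",
    "wald_iv",
    "subgroup_mr",
    "residual_stratify",
    "nonlinear_mr",
]

log = logging.getLogger(__name__)
_Z95 = stats.norm.ppf(0.975)


class WeakInstrumentError(RuntimeError):
    """First-stage association too weak for a ratio estimate."""


@dataclass
class StratumEstimate:
    """A causal estimate within one stratum of the cohort."""

    stratum: str
    n: int
    mean_exposure: float
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    first_stage_f: float = np.nan
    flagged_small: bool = False


@dataclass
class NonlinearResult:
    """Residual-stratified MR with heterogeneity and trend tests."""

    strata: List[StratumEstimate]
    Q: float
    Q_df: int
    Q_p: float
    metareg_slope: float
    metareg_slope_se: float
    nonlin_p: float
    pooled_beta: float = np.nan


# --------------------------------------------------------------------------
# Instrument construction
# --------------------------------------------------------------------------

def build_prs(cohort: Cohort, effects: Optional[np.ndarray] = None) -> np.ndarray:
    """Unweighted polygenic score: exposure-increasing allele count.

    Each SNV's dose is oriented so its effect on the exposure is positive
    (doses at negative-effect SNVs count the other allele, 2 - g).  Missing
    doses are mean-imputed per SNV and logged.  Integer-valued in
    [0, 2*n_snvs] when no imputation occurs.
    """
    g = np.asarray(cohort.genotypes, float).copy()
    if np.isnan(g).any():
        n_missing = int(np.isnan(g).sum())
        log.info("build_prs: mean-imputing %d missing dose(s)", n_missing)
        col_means = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = col_means[idx[1]]
    eff = np.asarray(effects if effects is not None else cohort.snv_effects)
    oriented = np.where(eff < 0, 2.0 - g, g)
    return oriented.sum(axis=1)


def _ols(y: np.ndarray, X: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """OLS coefficients and their classical SEs (first column of interest)."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(X.shape[0] - rank, 1)
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.clip(np.diag(XtX_inv), 0.0, None) * sigma2)
    return coef, se


def _design(
    data: pd.DataFrame, covariates: Sequence[str], score: np.ndarray
) -> np.ndarray:
    cols = [score, np.ones(len(data))]
    for c in covariates:
        v = data[c].to_numpy(float)
        if c in ("center", "month"):  # categorical -> dummies
            for level in np.unique(v)[1:]:
                cols.append((v == level).astype(float))
        else:
            cols.append(v)
    return np.column_stack(cols)


# --------------------------------------------------------------------------
# Wald ratio
# --------------------------------------------------------------------------

def wald_iv(
    cohort_or_data,
    score: np.ndarray,
    covariates: Optional[Sequence[str]] = None,
    stratum: str = "overall",
    min_first_stage_t: float = 1.0,
) -> StratumEstimate:
    """Covariate-adjusted Wald ratio.

    Ratio of the reduced-form coefficient (outcome ~ score + covariates) to
    the first-stage coefficient (exposure ~ score + covariates); by the
    Frisch-Waugh-Lovell theorem this equals the 2SLS point estimate with the
    score as single instrument.  SE by the first-order delta method; 95% CI
    normal.  Raises :class:`WeakInstrumentError` when the first-stage |t|
    falls below ``min_first_stage_t``.
    """
    data = cohort_or_data.data if isinstance(cohort_or_data, Cohort) else cohort_or_data
    score = np.asarray(score, float)
    if np.allclose(score, score[0]):
        raise WeakInstrumentError("instrument score is constant")
    if covariates is None:
        covariates = [c for c in data.columns
                      if c not in ("exposure", "outcome")]
    X = _design(data, covariates, score)
    cx, sx = _ols(data["exposure"].to_numpy(float), X)
    cy, sy = _ols(data["outcome"].to_numpy(float), X)
    num, num_se = cy[0], sy[0]
    den, den_se = cx[0], sx[0]
    t_first = abs(den) / den_se
    f_first = t_first**2
    if t_first < min_first_stage_t:
        raise WeakInstrumentError(
            f"first-stage |t| = {t_first:.2f} (F = {f_first:.2f})"
        )
    beta = num / den
    se = abs(beta) * np.sqrt((num_se / num) ** 2 + (den_se / den) ** 2) \
        if num != 0 else num_se / abs(den)
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return StratumEstimate(
        stratum=stratum, n=len(data),
        mean_exposure=float(data["exposure"].mean()),
        beta=float(beta), se=float(se),
        ci_low=float(beta - _Z95 * se), ci_high=float(beta + _Z95 * se),
        p=p, first_stage_f=float(f_first),
    )


# --------------------------------------------------------------------------
# Subgroups
# --------------------------------------------------------------------------

def _strata_masks(
    data: pd.DataFrame, scheme: str, age_cut: float = 65.0
) -> List[Tuple[str, np.ndarray, Optional[str]]]:
    """(label, mask, covariate-to-drop) triples for a stratification scheme."""
    if scheme == "sex":
        sex = data["sex"].to_numpy()
        return [("male", sex == 1, "sex"), ("female", sex == 0, "sex")]
    if scheme == "age_band":
        age = data["age"].to_numpy()
        # closed lower bound: a person aged exactly age_cut goes to the
        # older band
        return [(f"age_lt_{age_cut:g}", age < age_cut, "age"),
                (f"age_ge_{age_cut:g}", age >= age_cut, "age")]
    if scheme == "menopause":
        female = data["sex"].to_numpy() == 0
        post = data["postmenopausal"].to_numpy() == 1
        return [("premenopausal", female & ~post, "postmenopausal"),
                ("postmenopausal", female & post, "postmenopausal")]
    raise ValueError(f"unknown scheme {scheme!r}")


def subgroup_mr(
    cohort: Cohort,
    score: np.ndarray,
    scheme: str,
    age_cut: float = 65.0,
    min_n: int = 500,
    covariates: Optional[Sequence[str]] = None,
) -> List[StratumEstimate]:
    """Wald-ratio MR within each stratum of a stratification scheme.

    The stratification covariate is dropped from the adjustment set; strata
    with fewer than ``min_n`` members are flagged, empty strata skipped.
    """
    data = cohort.data
    if covariates is None:
        covariates = [c for c in data.columns
                      if c not in ("exposure", "outcome")]
    out = []
    for label, mask, drop in _strata_masks(data, scheme, age_cut):
        if mask.sum() == 0:
            log.warning("subgroup_mr: stratum %s empty; skipped", label)
            continue
        covs = [c for c in covariates if c != drop]
        if scheme == "menopause":
            covs = [c for c in covs if c != "sex"]  # females only
        est = wald_iv(data.loc[mask].reset_index(drop=True), score[mask],
                      covariates=covs, stratum=label)
        est.flagged_small = bool(mask.sum() < min_n)
        out.append(est)
    return out


# --------------------------------------------------------------------------
# Residual stratification and nonlinear MR
# --------------------------------------------------------------------------

def residual_stratify(
    cohort: Cohort,
    score: np.ndarray,
    n_strata: int = 4,
    mode: str = "fitted",
) -> Tuple[np.ndarray, np.ndarray]:
    """Stratum assignments and residual exposure.

    The genetic contribution is the first-stage slope times the score
    (``mode='fitted'``, default) or the raw score (``mode='raw'``),
    mean-centered; the residual is the observed exposure minus that
    quantity.  Quantile cut at sample quantiles with ties going to the
    lower stratum; stratum sizes differ by at most one.
    """
    data = cohort.data
    x = data["exposure"].to_numpy(float)
    score = np.asarray(score, float)
    if mode == "fitted":
        X = np.column_stack([score, np.ones_like(score)])
        coef, _ = _ols(x, X)
        contrib = coef[0] * score
    elif mode == "raw":
        contrib = score.astype(float)
    else:
        raise ValueError("mode must be 'fitted' or 'raw'")
    residual = x - (contrib - contrib.mean())
    n = residual.size
    order = np.argsort(residual, kind="stable")
    sizes = [n // n_strata + (1 if i < n % n_strata else 0)
             for i in range(n_strata)]
    assignment = np.empty(n, dtype=int)
    start = 0
    for q, size in enumerate(sizes):
        assignment[order[start:start + size]] = q
        start += size
    return assignment, residual


def nonlinear_mr(
    cohort: Cohort,
    score: np.ndarray,
    n_strata: int = 4,
    covariates: Optional[Sequence[str]] = None,
    stratify_mode: str = "fitted",
) -> NonlinearResult:
    """Residual-stratified nonlinear MR.

    Wald-ratio estimates per residual-exposure quantile stratum (full
    covariate set), Cochran's Q against the IVW pooled estimate
    (chi-square, n_strata-1 df), and a weighted meta-regression of stratum
    estimates on stratum mean exposure whose slope Wald test is the
    nonlinearity p-value.  Weak-instrument strata are dropped with a log
    message and the degrees of freedom adjusted.
    """
    assignment, _ = residual_stratify(cohort, score, n_strata, stratify_mode)
    data = cohort.data
    estimates: List[StratumEstimate] = []
    for q in range(n_strata):
        mask = assignment == q
        try:
            est = wald_iv(data.loc[mask].reset_index(drop=True), score[mask],
                          covariates=covariates, stratum=f"Q{q + 1}")
        except WeakInstrumentError as err:
            log.warning("nonlinear_mr: stratum Q%d dropped (%s)", q + 1, err)
            continue
        estimates.append(est)
    if len(estimates) < 3:
        raise ValueError("nonlinear MR needs >= 3 strata with valid estimates")

    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    means = np.array([e.mean_exposure for e in estimates])
    w = 1.0 / ses**2
    pooled = float(np.sum(w * betas) / np.sum(w))
    Q = float(np.sum(w * (betas - pooled) ** 2))
    q_df = len(estimates) - 1
    q_p = float(stats.chi2.sf(Q, q_df))

    X = np.column_stack([np.ones_like(means), means])
    A = X.T @ (X * w[:, None])
    theta = np.linalg.solve(A, (X * w[:, None]).T @ betas)
    cov = np.linalg.inv(A)
    slope, slope_se = float(theta[1]), float(np.sqrt(cov[1, 1]))
    nonlin_p = float(2 * stats.norm.sf(abs(slope) / slope_se))

    return NonlinearResult(
        strata=estimates, Q=Q, Q_df=q_df, Q_p=q_p,
        metareg_slope=slope, metareg_slope_se=slope_se,
        nonlin_p=nonlin_p, pooled_beta=pooled,
    )
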