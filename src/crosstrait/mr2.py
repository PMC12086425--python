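"""Two-sample Mendelian randomization estimators and diagnostics.

Implements the standard battery on a harmonized instrument set: IVW (the
primary estimator; multiplicative random effects by default), MR-Egger
regression with its directional-pleiotropy intercept, the weighted median
with bootstrap SE, an MR-PRESSO-style global residual test with outlier
correction, leave-one-out, Steiger directionality filtering, multivariable
IVW, and confounder-associated instrument exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import InstrumentSet

__all__ = [
    "MRFit",
    "ivw",
    "egger",
    "weighted_median",
    "mr_presso",
    "leave_one_out",
    "steiger_filter",
    "mvmr_ivw",
    "exclude_confounder_ivs",
    "EmptyInstrumentError",
]

log = logging.getLogger(__name__)
_Z95 = stats.norm.ppf(0.975)


class EmptyInstrumentError(ValueError):
    """Raised when an estimator receives no instruments."""


@dataclass
class MRFit:
    """A causal-effect estimate (outcome SD per exposure SD) from MR."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_iv: int
    diagnostics: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_iv >= 1 and np.isfinite(self.beta):
            assert self.ci_low <= self.beta <= self.ci_high


def _arrays(iv: InstrumentSet) -> Tuple[np.ndarray, ...]:
    if iv.n_iv == 0:
        raise EmptyInstrumentError("instrument set is empty")
    df = iv.df
    return (df["beta_x"].to_numpy(float), df["se_x"].to_numpy(float),
            df["beta_y"].to_numpy(float), df["se_y"].to_numpy(float))


def _fit_from(method: str, beta: float, se: float, n_iv: int,
              diagnostics: Optional[Dict] = None) -> MRFit:
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else 1.0
    return MRFit(method=method, beta=float(beta), se=float(se),
                 ci_low=float(beta - _Z95 * se), ci_high=float(beta + _Z95 * se),
                 p=p, n_iv=n_iv, diagnostics=diagnostics or {})


# --------------------------------------------------------------------------
# IVW
# --------------------------------------------------------------------------

def ivw(iv: InstrumentSet, model: str = "random") -> MRFit:
    """Inverse-variance-weighted estimate.

    ``beta = sum(w*bx*by) / sum(w*bx^2)`` with ``w = 1/se_y^2``; with one
    instrument this reduces to the Wald ratio by/bx.  ``model='random'``
    (multiplicative random effects, the default) inflates the fixed-effect SE
    by sqrt(max(1, Q/(n_iv-1))); ``model='fixed'`` leaves it untouched.
    Cochran's Q and its p-value are reported as heterogeneity diagnostics.
    """
    bx, _, by, se_y = _arrays(iv)
    w = 1.0 / se_y**2
    denom = np.sum(w * bx * bx)
    beta = np.sum(w * bx * by) / denom
    se_fixed = np.sqrt(1.0 / denom)
    n = bx.size
    resid = by - beta * bx
    Q = float(np.sum(w * resid * resid))
    q_df = max(n - 1, 1)
    q_p = float(stats.chi2.sf(Q, q_df)) if n > 1 else 1.0
    se = se_fixed
    if model == "random" and n > 1:
        se = se_fixed * np.sqrt(max(1.0, Q / (n - 1)))
    elif model not in ("random", "fixed"):
        raise ValueError("model must be 'random' or 'fixed'")
    return _fit_from(f"ivw_{model}" if n > 1 else "wald_ratio", beta, se, n,
                     {"Q": Q, "Q_df": q_df, "Q_p": q_p})


# --------------------------------------------------------------------------
# MR-Egger
# --------------------------------------------------------------------------

def egger(iv: InstrumentSet) -> MRFit:
    """MR-Egger regression: WLS of by on bx with a free intercept.

    The slope is the pleiotropy-robust causal estimate (InSIDE assumption);
    the intercept and its p-value diagnose directional pleiotropy.  Requires
    the exposure-positive orientation already enforced by harmonization.
    """
    bx, _, by, se_y = _arrays(iv)
    n = bx.size
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    if np.allclose(bx, bx[0]):
        raise np.linalg.LinAlgError("degenerate design: all beta_x equal")
    w = 1.0 / se_y**2
    X = np.column_stack([np.ones(n), bx])
    A = X.T @ (X * w[:, None])
    c = (X * w[:, None]).T @ by
    theta = np.linalg.solve(A, c)
    resid = by - X @ theta
    # multiplicative overdispersion, floored at 1 (random-effects Egger)
    phi = max(1.0, float(np.sum(w * resid**2) / (n - 2)))
    cov = np.linalg.inv(A) * phi
    se_int, se_slope = np.sqrt(np.diag(cov))
    int_p = float(2 * stats.t.sf(abs(theta[0]) / se_int, n - 2))
    fit = _fit_from("egger", theta[1], se_slope, n)
    fit.p = float(2 * stats.t.sf(abs(theta[1]) / se_slope, n - 2))
    fit.diagnostics = {
        "egger_intercept": float(theta[0]),
        "egger_intercept_se": float(se_int),
        "egger_intercept_p": int_p,
    }
    return fit


# --------------------------------------------------------------------------
# Weighted median
# --------------------------------------------------------------------------

def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / np.sum(weights)
    cum = np.cumsum(w) - w / 2.0
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(cum, 0.5))
    # interpolate between the bracketing ratios
    lo, hi = cum[j - 1], cum[j]
    t = (0.5 - lo) / (hi - lo)
    return float(r[j - 1] + t * (r[j] - r[j - 1]))


def weighted_median(
    iv: InstrumentSet, n_boot: int = 1000, seed: int = 0
) -> MRFit:
    """Weighted median of per-instrument Wald ratios.

    Weights are bx^2/se_y^2 (inverse variance of the ratio, leading order);
    the estimate is the ratio at which the cumulative weight crosses one
    half, linearly interpolated.  Consistent when valid instruments carry
    >50% of the weight.  SE by seeded parametric bootstrap.
    """
    bx, se_x, by, se_y = _arrays(iv)
    keep = bx != 0.0
    if not keep.all():
        log.info("weighted_median: excluded %d IV(s) with beta_x == 0",
                 int((~keep).sum()))
    bx, se_x, by, se_y = bx[keep], se_x[keep], by[keep], se_y[keep]
    n = bx.size
    if n < 3:
        raise ValueError("weighted median needs at least 3 usable instruments")
    ratios = by / bx
    weights = bx**2 / se_y**2
    est = _weighted_median_point(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxb = bx + rng.normal(0.0, se_x)
        byb = by + rng.normal(0.0, se_y)
        ok = bxb != 0
        boots[b] = _weighted_median_point(byb[ok] / bxb[ok],
                                          bxb[ok] ** 2 / se_y[ok] ** 2)
    se = float(np.std(boots, ddof=1))
    return _fit_from("weighted_median", est, se, n)


# --------------------------------------------------------------------------
# MR-PRESSO
# --------------------------------------------------------------------------

def mr_presso(
    iv: InstrumentSet,
    n_sim: int = 5000,
    seed: int = 0,
    outlier_alpha: Optional[float] = None,
) -> MRFit:
    """Residual-sum-of-squares pleiotropy test with outlier correction.

    The observed RSS sums, over instruments, the weighted squared deviation
    of by_j from the leave-one-out IVW prediction beta(-j)*bx_j.  Its null
    distribution is simulated parametrically (both betas redrawn at their
    standard errors under the no-pleiotropy model), giving a global p.
    Per-instrument outlier p-values use the same construction; instruments
    below the Bonferroni threshold (default 0.05/n_iv) are flagged and an
    outlier-corrected IVW is returned (the uncorrected fit when none are
    found).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be at least 100")
    bx, se_x, by, se_y = _arrays(iv)
    n = bx.size
    if n < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if outlier_alpha is None:
        outlier_alpha = 0.05 / n
    w = 1.0 / se_y**2

    def loo_betas(bxa: np.ndarray, bya: np.ndarray) -> np.ndarray:
        num = np.sum(w * bxa * bya) - w * bxa * bya
        den = np.sum(w * bxa * bxa) - w * bxa * bxa
        return num / den

    beta_loo = loo_betas(bx, by)
    obs_terms = w * (by - beta_loo * bx) ** 2
    rss_obs = float(np.sum(obs_terms))

    rng = np.random.default_rng(seed)
    exceed = 0
    term_exceed = np.zeros(n)
    for _ in range(n_sim):
        bxs = bx + rng.normal(0.0, se_x)
        bys = beta_loo * bxs + rng.normal(0.0, se_y)
        bl = loo_betas(bxs, bys)
        terms = w * (bys - bl * bxs) ** 2
        if np.sum(terms) >= rss_obs:
            exceed += 1
        term_exceed += terms >= obs_terms
    global_p = (exceed + 1) / (n_sim + 1)
    outlier_p = (term_exceed + 1) / (n_sim + 1)
    outliers = np.flatnonzero(outlier_p < outlier_alpha)
    outlier_ids = [str(iv.df["snp"].iloc[int(j)]) for j in outliers]

    base = ivw(iv)
    if outliers.size and outliers.size < n:
        mask = np.ones(n, bool)
        mask[outliers] = False
        corrected = ivw(iv.subset(mask))
        fit = _fit_from("mr_presso_corrected", corrected.beta, corrected.se,
                        int(mask.sum()))
    else:
        fit = _fit_from("mr_presso", base.beta, base.se, n)
    fit.diagnostics = {
        "global_rss": rss_obs,
        "global_rss_p": float(global_p),
        "outlier_ids": outlier_ids,
        "outlier_p": {sid: float(outlier_p[int(j)])
                      for sid, j in zip(outlier_ids, outliers)},
        "uncorrected_beta": base.beta,
    }
    return fit


# --------------------------------------------------------------------------
# Sensitivity analyses
# --------------------------------------------------------------------------

def leave_one_out(iv: InstrumentSet) -> List[MRFit]:
    """IVW refits each omitting one instrument.

    Each fit's diagnostics record the omitted SNV and an ``influential``
    flag set when omission moves the estimate by more than one pooled SE.
    """
    n = iv.n_iv
    if n < 2:
        raise ValueError("leave-one-out needs at least 2 instruments")
    full = ivw(iv)
    fits = []
    for j in range(n):
        mask = np.ones(n, bool)
        mask[j] = False
        f = ivw(iv.subset(mask))
        pooled_se = np.hypot(full.se, f.se)
        f.diagnostics["omitted"] = str(iv.df["snp"].iloc[j])
        f.diagnostics["influential"] = bool(
            abs(f.beta - full.beta) > pooled_se
        )
        fits.append(f)
    return fits


def steiger_filter(
    iv: InstrumentSet,
    n_x: Optional[int] = None,
    n_y: Optional[int] = None,
    alpha: float = 0.05,
) -> Tuple[InstrumentSet, "list[dict]"]:
    """Drop instruments explaining more outcome than exposure variance.

    Per SNV the variance explained is r2 = z^2 / (z^2 + n); an instrument is
    removed when r2_y > r2_x with Steiger-test (Fisher z) p < alpha.
    Returns the filtered set and a report of removals.
    """
    bx, se_x, by, se_y = _arrays(iv)
    n_x_arr = (np.full(bx.size, n_x, float) if n_x is not None
               else iv.df["n_x"].to_numpy(float))
    n_y_arr = (np.full(bx.size, n_y, float) if n_y is not None
               else iv.df["n_y"].to_numpy(float))
    zx = bx / se_x
    zy = by / se_y
    r2x = zx**2 / (zx**2 + n_x_arr)
    r2y = zy**2 / (zy**2 + n_y_arr)
    rx, ry = np.sqrt(r2x), np.sqrt(r2y)
    zstat = (np.arctanh(np.clip(rx, 0, 1 - 1e-12))
             - np.arctanh(np.clip(ry, 0, 1 - 1e-12))) / np.sqrt(
        1.0 / (n_x_arr - 3) + 1.0 / (n_y_arr - 3))
    p = 2 * stats.norm.sf(np.abs(zstat))
    discordant = (r2y > r2x) & (p < alpha)
    report = [
        {"snp": str(iv.df["snp"].iloc[j]), "r2_x": float(r2x[j]),
         "r2_y": float(r2y[j]), "steiger_p": float(p[j]),
         "reason": "discordant"}
        for j in np.flatnonzero(discordant)
    ]
    filtered = iv.subset(~discordant)
    if report:
        filtered.excluded = pd.concat(
            [filtered.excluded,
             pd.DataFrame([{"snp": r["snp"], "reason": "steiger_discordant"}
                           for r in report])],
            ignore_index=True,
        )
    return filtered, report


def mvmr_ivw(
    beta_exposures: np.ndarray,
    beta_y: np.ndarray,
    se_y: np.ndarray,
    exposure_names: Optional[Sequence[str]] = None,
) -> List[MRFit]:
    """Multivariable IVW: WLS of by on the exposure-beta matrix, no intercept.

    ``beta_exposures`` is (n_iv, n_exposures).  Returns one MRFit per
    exposure (its direct effect conditional on the others).
    """
    B_all = np.atleast_2d(np.asarray(beta_exposures, float))
    by = np.asarray(beta_y, float)
    se = np.asarray(se_y, float)
    n, k = B_all.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} instruments for {k} exposures")
    names = (list(exposure_names) if exposure_names is not None
             else [f"exposure_{i + 1}" for i in range(k)])
    # an exposure with no instrument effects carries no information; drop it
    # (its own estimate is undefined) rather than failing the joint fit
    active = [i for i in range(k) if np.any(B_all[:, i] != 0.0)]
    dropped = [i for i in range(k) if i not in active]
    if dropped:
        log.warning("mvmr_ivw: exposure(s) %s have all-zero betas; dropped",
                    [names[i] for i in dropped])
    B = B_all[:, active]
    if B.shape[1] == 0 or np.linalg.matrix_rank(B) < B.shape[1]:
        raise np.linalg.LinAlgError("exposure beta matrix is rank-deficient")
    w = 1.0 / se**2
    A = B.T @ (B * w[:, None])
    c = (B * w[:, None]).T @ by
    theta = np.linalg.solve(A, c)
    resid = by - B @ theta
    phi = max(1.0, float(np.sum(w * resid**2) / max(n - B.shape[1], 1)))
    cov = np.linalg.inv(A) * phi
    ses = np.sqrt(np.diag(cov))
    out = []
    pos = {i: j for j, i in enumerate(active)}
    for i in range(k):
        if i in pos:
            j = pos[i]
            out.append(_fit_from(f"mvmr_ivw[{names[i]}]", theta[j], ses[j], n))
        else:
            out.append(MRFit(method=f"mvmr_ivw[{names[i]}]", beta=np.nan,
                             se=np.nan, ci_low=np.nan, ci_high=np.nan,
                             p=np.nan, n_iv=n,
                             diagnostics={"dropped": "all-zero betas"}))
    return out


def exclude_confounder_ivs(
    iv: InstrumentSet, blocklist: Iterable[str]
) -> InstrumentSet:
    """Remove instruments on a user-supplied confounder-associated list."""
    blocklist = list(blocklist)
    if not blocklist:
        return iv
    out = iv.drop_snvs(blocklist, reason="confounder_associated")
    log.info("excluded %d confounder-associated IV(s)", iv.n_iv - out.n_iv)
    return out
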