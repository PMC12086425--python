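"""Cross-trait meta-analysis: a two-trait pleiotropy scan.

Per SNV the two traits' z-scores are decorrelated by the inverse square root
of the null correlation matrix C (sample overlap / shared environment), and
a variance-component likelihood-ratio statistic tests tau^2 = 0 versus
tau^2 > 0 in

    u ~ Normal(0, I + tau^2 * Omega~),   u = C^{-1/2} (z1, z2),

where Omega~ is the (decorrelated, unit-trace) genetic covariance between
the traits — so power is aimed along the genetic direction while the free
null correlation keeps false positives controlled under overlap.  P-values
come from seeded Monte-Carlo draws of the statistic under the null (the
null law is SNV-independent, so one draw set serves a whole scan); the
analytic 50:50 chi2(0)/chi2(1) boundary mixture extends the far tail where
the draws are exhausted and stands in entirely when no draws are supplied.
A GLS omnibus chi-square (z' C^{-1} z, 2 df) is available as a cross-check
mode.

Index SNVs come from PLINK-style clumping of the pleiotropy p-values
(p1 5e-8, p2 1e-5, r2 0.2, 500 kb); a locus is significant when the index
passes P_pleio < 5e-8 with both single-trait P < 1e-5, and novel when it is
driven by neither trait alone, tags no known hit at r2 >= 0.2, and has no
genome-wide-significant single-trait neighbor within 500 kb.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .ldpanel import LDPanel
from .ldsc import LdscFit
from .sumstats import SumStats, clump, harmonize

__all__ = [
    "NullCorr",
    "PleioHit",
    "estimate_null_corr",
    "pleio_stat",
    "pleio_stat_array",
    "null_stat_draws",
    "gls_omnibus",
    "pleio_scan",
    "classify_novel",
]

log = logging.getLogger(__name__)

P_PLEIO_THRESH = 5e-8
P_SINGLE_THRESH = 1e-5
LOCUS_HALF_WINDOW = 500_000  # bp


@dataclass
class NullCorr:
    """Null (non-genetic) correlation of the two traits' z-scores.

    ``C`` is the 2x2 unit-diagonal correlation under no genetic signal;
    ``omega`` the genetic covariance matrix [[h2_1, gencov], [gencov, h2_2]]
    orienting the alternative.
    """

    C: np.ndarray
    omega: np.ndarray
    source: str = "intercepts"

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, float)
        self.omega = np.asarray(self.omega, float)
        if not np.allclose(self.C, self.C.T) or not np.allclose(np.diag(self.C), 1.0):
            raise ValueError("C must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(self.C).min() <= 0:
            raise ValueError("C must be positive definite")

    def decorrelated_omega(self) -> Tuple[np.ndarray, np.ndarray]:
        """Eigen-decomposition (values, vectors) of unit-trace C^-1/2 Omega C^-1/2."""
        lam, U = np.linalg.eigh(self.C)
        C_isqrt = U @ np.diag(1.0 / np.sqrt(lam)) @ U.T
        om = C_isqrt @ self.omega @ C_isqrt
        d, V = np.linalg.eigh(om)
        d = np.clip(d, 0.0, None)
        tr = d.sum()
        if tr <= 1e-12:
            log.warning("degenerate genetic covariance; using isotropic Omega~")
            d = np.array([0.5, 0.5])
            V = np.eye(2)
        else:
            d = d / tr
        return d, V

    def c_inv_sqrt(self) -> np.ndarray:
        lam, U = np.linalg.eigh(self.C)
        return U @ np.diag(1.0 / np.sqrt(lam)) @ U.T


def _truncated_corr_map(r: float, t1: float, t2: float,
                        n_nodes: int = 48) -> float:
    """Pearson corr of a unit BVN(r) truncated to the box |x|<t1, |y|<t2."""
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    xs, ws1 = t1 * nodes, t1 * weights
    ys, ws2 = t2 * nodes, t2 * weights
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    W = np.outer(ws1, ws2)
    det = 1.0 - r * r
    dens = np.exp(-(X**2 - 2 * r * X * Y + Y**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det))
    mass = np.sum(W * dens)
    exy = np.sum(W * dens * X * Y) / mass
    exx = np.sum(W * dens * X * X) / mass
    eyy = np.sum(W * dens * Y * Y) / mass
    return float(exy / np.sqrt(exx * eyy))


def _truncated_sd(x: np.ndarray, t: float) -> float:
    """SD of a centred normal inferred from its box-truncated second moment.

    Solves E[x^2 | |x| < t] = observed for the untruncated SD; closed-form
    moment for a doubly truncated normal.
    """
    from scipy.optimize import brentq

    obs = float(np.mean(x * x))

    def moment(s: float) -> float:
        a = t / s
        z = 2 * stats.norm.cdf(a) - 1
        return s * s * (1 - 2 * a * stats.norm.pdf(a) / z)

    if obs >= moment(50.0):
        return 50.0
    lo = 1e-3
    if obs <= moment(lo):
        return lo
    return float(brentq(lambda s: moment(s) - obs, lo, 50.0, xtol=1e-8))


def _empirical_null_corr(z1: np.ndarray, z2: np.ndarray,
                         t: float = 1.96) -> float:
    """Noise covariance of two z-score sets from their null-region SNVs.

    SNVs with |z| < t in both traits are approximately bivariate normal
    with per-trait variances inflated by polygenic signal and cross-
    covariance equal to the sought overlap term c.  The per-trait SDs are
    inverted from the truncated second moments, the correlation from the
    (variance-rescaled) truncated-correlation map; c is then corr * s1 * s2.
    """
    from scipy.optimize import brentq

    mask = (np.abs(z1) < t) & (np.abs(z2) < t)
    if mask.sum() < 20:
        raise ValueError("too few null SNVs for empirical mode")
    x, y = z1[mask], z2[mask]
    s1 = _truncated_sd(x, t)
    s2 = _truncated_sd(y, t)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    r_obs = float(np.clip(r_obs, -0.985, 0.985))
    t1, t2 = t / s1, t / s2
    f = lambda r: _truncated_corr_map(r, t1, t2) - r_obs
    lo, hi = -0.995, 0.995
    if f(lo) > 0:
        r_tot = lo
    elif f(hi) < 0:
        r_tot = hi
    else:
        r_tot = float(brentq(f, lo, hi, xtol=1e-6))
    return float(r_tot * s1 * s2)


def estimate_null_corr(
    x: SumStats,
    y: SumStats,
    ldsc_fit: LdscFit,
    mode: str = "intercepts",
) -> NullCorr:
    """Estimate the null z-score correlation between two traits.

    ``mode='intercepts'`` takes the bivariate LD-score regression
    cross-intercept; ``mode='empirical'`` the correlation of z-scores over
    SNVs with |z| < 1.96 in both traits, corrected for the attenuation that
    box truncation of a bivariate normal induces (exact inversion of the
    truncated-correlation map).  Off-diagonals at or beyond +/-1 are
    clipped to +/-0.99 with a warning.  The genetic direction matrix comes
    from the same LDSC fit (non-PSD estimates are projected to the PSD
    cone).
    """
    if mode == "intercepts":
        c = float(ldsc_fit.cross_intercept)
    elif mode == "empirical":
        merged = pd.merge(x.df[["SNP", "BETA", "SE"]], y.df[["SNP", "BETA", "SE"]],
                          on="SNP", suffixes=("_1", "_2"))
        z1 = (merged["BETA_1"] / merged["SE_1"]).to_numpy()
        z2 = (merged["BETA_2"] / merged["SE_2"]).to_numpy()
        c = _empirical_null_corr(z1, z2)
    else:
        raise ValueError("mode must be 'intercepts' or 'empirical'")
    if abs(c) >= 1.0:
        log.warning("null correlation %.3f clipped to +/-0.99", c)
        c = float(np.clip(c, -0.99, 0.99))
    C = np.array([[1.0, c], [c, 1.0]])
    h2_1 = max(float(ldsc_fit.h2), 0.0)
    h2_2 = max(float(ldsc_fit.h2_2 if ldsc_fit.h2_2 is not None else 0.0), 0.0)
    gc = float(ldsc_fit.gencov or 0.0)
    omega = np.array([[h2_1, gc], [gc, h2_2]])
    w, V = np.linalg.eigh(omega)
    omega = V @ np.diag(np.clip(w, 0.0, None)) @ V.T
    return NullCorr(C=C, omega=omega, source=mode)


# --------------------------------------------------------------------------
# The variance-component LRT
# --------------------------------------------------------------------------

def _ll_diff_grid(v2: np.ndarray, d: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """2*(ll(tau) - ll(0)) for v2 (N, 2) across a tau grid; returns (N, T)."""
    s = 1.0 + taus[:, None] * d[None, :]              # (T, 2)
    # ll(tau)-ll(0) = -0.5 [ sum log s + v2 @ (1/s - 1) ]
    log_det = np.sum(np.log(s), axis=1)               # (T,)
    inv_m1 = 1.0 / s - 1.0                            # (T, 2)
    return -(log_det[None, :] + v2 @ inv_m1.T)        # (N, T)


_DEFAULT_TAU_GRID = np.concatenate([[0.0], np.geomspace(1e-4, 1e6, 241)])


def _stat_array(v2: np.ndarray, d: np.ndarray,
                taus: np.ndarray = _DEFAULT_TAU_GRID) -> np.ndarray:
    """Grid-maximized LRT statistic with one parabolic refinement in log-tau."""
    v2 = np.atleast_2d(v2)
    out = np.empty(v2.shape[0])
    chunk = 20_000
    for a in range(0, v2.shape[0], chunk):
        sl = slice(a, min(a + chunk, v2.shape[0]))
        g = _ll_diff_grid(v2[sl], d, taus)            # (n, T)
        best = np.argmax(g, axis=1)
        stat = g[np.arange(g.shape[0]), best]
        # parabolic refinement in log-tau for interior maxima
        interior = (best > 1) & (best < taus.size - 1)
        if interior.any():
            idx = np.flatnonzero(interior)
            b = best[idx]
            lt = np.log(taus[np.stack([b - 1, b, b + 1])])
            gv = np.stack([g[idx, b - 1], g[idx, b], g[idx, b + 1]])
            denom = (lt[0] - 2 * lt[1] + lt[2])
            with np.errstate(divide="ignore", invalid="ignore"):
                num = (gv[0] - gv[2]) * (lt[2] - lt[0]) / 4.0
                curst = gv[0] - 2 * gv[1] + gv[2]
                shift = np.where(np.abs(curst) > 1e-14, num / curst, 0.0)
            lt_star = np.clip(lt[1] + shift, lt[1] - (lt[1] - lt[0]),
                              lt[1] + (lt[2] - lt[1]))
            tau_star = np.exp(lt_star)
            s = 1.0 + tau_star[:, None] * d[None, :]
            g_star = -(np.sum(np.log(s), axis=1)
                       + np.sum(v2[sl][idx] * (1.0 / s - 1.0), axis=1))
            stat[idx] = np.maximum(stat[idx], g_star)
        out[sl] = np.maximum(stat, 0.0)
    return out


def _stat_scalar(v2: np.ndarray, d: np.ndarray) -> float:
    """High-precision LRT statistic for a single SNV (Brent in log-tau)."""

    def neg(lt: float) -> float:
        s = 1.0 + np.exp(lt) * d
        return float(np.sum(np.log(s)) + np.sum(v2 * (1.0 / s - 1.0)))

    res = minimize_scalar(neg, bounds=(-30.0, 30.0), method="bounded",
                          options={"xatol": 1e-12})
    return max(0.0, -float(res.fun))


def mixture_p(stat: np.ndarray) -> np.ndarray:
    """P-value from the 50:50 chi2(0)/chi2(1) boundary mixture."""
    stat = np.asarray(stat, float)
    p = np.where(stat <= 0.0, 1.0, 0.5 * stats.chi2.sf(stat, 1))
    return np.maximum(p, 5e-324)


def null_stat_draws(
    null_corr: NullCorr, n_draws: int = 1_000_000, seed: int = 0
) -> np.ndarray:
    """Sorted Monte-Carlo draws of the LRT statistic under the null."""
    d, _ = null_corr.decorrelated_omega()
    rng = np.random.default_rng(seed)
    v2 = rng.standard_normal((int(n_draws), 2)) ** 2
    return np.sort(_stat_array(v2, d))


def _refine_p(stat: np.ndarray, p_mix: np.ndarray,
              draws: Optional[np.ndarray]) -> np.ndarray:
    """Empirical null p-values from shared Monte-Carlo draws.

    With a single bivariate observation per SNV the asymptotic 50:50
    mixture is only a rough reference (the true point mass at zero depends
    on Omega~), so whenever null draws are available the p-value is the
    empirical exceedance probability; the analytic mixture serves as the
    far-tail extension once the draws are exhausted.
    """
    if draws is None or draws.size == 0:
        return p_mix
    n = draws.size
    k = n - np.searchsorted(draws, stat, side="left")
    emp = (k + 1) / (n + 1)
    return np.where(k > 0, emp, np.minimum(p_mix, 1.0 / (n + 1)))


def pleio_stat(
    z1: float,
    z2: float,
    null_corr: NullCorr,
    n_mc: int = 1_000_000,
    seed: int = 0,
    mc_draws: Optional[np.ndarray] = None,
) -> Tuple[float, float]:
    """Pleiotropy LRT statistic and p-value for one SNV.

    Decorrelates (z1, z2) by C^{-1/2} and maximizes the one-parameter
    variance-component likelihood over tau^2 >= 0.  The p-value is the
    empirical exceedance probability against seeded Monte-Carlo null draws
    (``mc_draws`` shares a precomputed set; the null law is the same for
    every SNV), falling back to the analytic 50:50 chi2(0)/chi2(1) mixture
    in the far tail where the draws are exhausted.  Passing an empty
    ``mc_draws`` array requests the analytic mixture alone.
    """
    d, V = null_corr.decorrelated_omega()
    u = null_corr.c_inv_sqrt() @ np.array([z1, z2], float)
    v2 = (V.T @ u) ** 2
    stat = _stat_scalar(v2, d)
    p = float(mixture_p(np.array([stat]))[0])
    if mc_draws is None and p < 1e-4:
        mc_draws = null_stat_draws(null_corr, n_mc, seed)
    if mc_draws is not None:
        p = float(_refine_p(np.array([stat]), np.array([p]), mc_draws)[0])
    return stat, p


def pleio_stat_array(
    z1: np.ndarray,
    z2: np.ndarray,
    null_corr: NullCorr,
    mc_draws: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized pleiotropy statistic and p-value over many SNVs."""
    d, V = null_corr.decorrelated_omega()
    Z = np.vstack([z1, z2])
    U = null_corr.c_inv_sqrt() @ Z
    v2 = (V.T @ U).T ** 2
    stat = _stat_array(v2, d)
    p = _refine_p(stat, mixture_p(stat), mc_draws)
    return stat, p


def gls_omnibus(
    z1: np.ndarray, z2: np.ndarray, null_corr: NullCorr
) -> Tuple[np.ndarray, np.ndarray]:
    """Fallback omnibus test: z' C^{-1} z on 2 df (overlap-aware GLS)."""
    Cinv = np.linalg.inv(null_corr.C)
    Z = np.vstack([np.atleast_1d(z1), np.atleast_1d(z2)])
    stat = np.einsum("in,ij,jn->n", Z, Cinv, Z)
    return stat, np.maximum(stats.chi2.sf(stat, 2), 5e-324)


# --------------------------------------------------------------------------
# Genome scan, significance and novelty
# --------------------------------------------------------------------------

@dataclass
class PleioHit:
    """An index SNV from the cross-trait scan with its locus annotations."""

    snp: str
    chr: int
    pos: int
    z1: float
    z2: float
    p_pleio: float
    p_trait1: float
    p_trait2: float
    window_start: int
    window_end: int
    significant: bool
    novel: Optional[bool] = None
    novelty_failures: List[str] = field(default_factory=list)
    nearest_known: List[str] = field(default_factory=list)


def pleio_scan(
    x: SumStats,
    y: SumStats,
    panel: LDPanel,
    null_corr: NullCorr,
    mc_draws: Optional[np.ndarray] = None,
    p1: float = P_PLEIO_THRESH,
    p2: float = P_SINGLE_THRESH,
    r2: float = 0.2,
    kb: float = 500.0,
) -> List[PleioHit]:
    """Genome scan for pleiotropic index SNVs.

    Computes the pleiotropy p per SNV, clumps (p1 5e-8, p2 1e-5, r2 0.2,
    +/-500 kb), and applies the significance filter (index P_pleio < p1 and
    both single-trait P < p2).  Returns every index with its flags; locus
    windows are +/-500 kb closed intervals.
    """
    hz = harmonize(x, y)
    df = hz.df
    z1 = (df["beta_x"] / df["se_x"]).to_numpy()
    z2 = (df["beta_y"] / df["se_y"]).to_numpy()
    _, p_pleio = pleio_stat_array(z1, z2, null_corr, mc_draws)

    p_x = dict(zip(x.df["SNP"], x.df["P"]))
    p_y = dict(zip(y.df["SNP"], y.df["P"]))

    scan_df = pd.DataFrame(
        {
            "SNP": df["snp"], "CHR": df["chr"], "POS": df["pos"],
            "EA": df["ea"], "OA": df["oa"], "EAF": df["eaf_x"],
            "BETA": z1, "SE": 1.0, "P": p_pleio, "N": df["n_x"],
        }
    )
    pseudo = SumStats(trait="pleio", df=scan_df)
    idx = clump(pseudo, panel, p1=p1, p2=p2, r2=r2, kb=kb)

    pmap = dict(zip(scan_df["SNP"], p_pleio))
    zmap1 = dict(zip(df["snp"], z1))
    zmap2 = dict(zip(df["snp"], z2))
    hits = []
    for r in idx.itertuples(index=False):
        snp = str(r.index_snp)
        pt1 = float(p_x.get(snp, np.nan))
        pt2 = float(p_y.get(snp, np.nan))
        pp = float(pmap[snp])
        hits.append(
            PleioHit(
                snp=snp, chr=int(r.chr), pos=int(r.pos),
                z1=float(zmap1[snp]), z2=float(zmap2[snp]),
                p_pleio=pp, p_trait1=pt1, p_trait2=pt2,
                window_start=max(1, int(r.pos) - LOCUS_HALF_WINDOW),
                window_end=int(r.pos) + LOCUS_HALF_WINDOW,
                significant=bool(pp < p1 and pt1 < p2 and pt2 < p2),
            )
        )
    return hits


def classify_novel(
    hits: Sequence[PleioHit],
    known1: Iterable[str],
    known2: Iterable[str],
    panel: LDPanel,
    x: Optional[SumStats] = None,
    y: Optional[SumStats] = None,
    r2_known: float = 0.2,
    gw_sig: float = P_PLEIO_THRESH,
) -> List[PleioHit]:
    """Flag novel pleiotropic SNVs among significant hits.

    A significant index is novel iff (1) it is driven by neither trait
    alone (both single-trait p between 5e-8 and 1e-5), (2) it is not in LD
    (r^2 >= ``r2_known``) with any known hit of either trait, and (3) no
    neighbor within +/-500 kb reaches genome-wide significance in either
    single-trait GWAS (checked when the summary statistics are supplied).
    Failed clauses are recorded per hit.
    """
    known = [str(s) for s in known1] + [str(s) for s in known2]
    for hit in hits:
        if not hit.significant:
            hit.novel = False
            hit.novelty_failures = ["not_significant"]
            continue
        failures: List[str] = []
        if not (gw_sig < hit.p_trait1 < P_SINGLE_THRESH
                and gw_sig < hit.p_trait2 < P_SINGLE_THRESH):
            failures.append("single_trait_driven")
        tagged = []
        for ksnp in known:
            r2v = panel.r2(hit.snp, ksnp)
            if r2v is not None and r2v >= r2_known:
                tagged.append(ksnp)
        if tagged:
            failures.append("ld_with_known")
        hit.nearest_known = tagged
        if x is not None and y is not None:
            for ss in (x, y):
                sub = ss.df[(ss.df["CHR"] == hit.chr)
                            & (ss.df["POS"] >= hit.window_start)
                            & (ss.df["POS"] <= hit.window_end)
                            & (ss.df["SNP"] != hit.snp)]
                if (sub["P"] < gw_sig).any():
                    failures.append("gw_significant_neighbor")
                    break
        hit.novel = not failures
        hit.novelty_failures = failures
    return list(hits)
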