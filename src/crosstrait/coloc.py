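"""Bayesian fine-mapping and two-trait colocalization at a locus.

Per-variant evidence is the Wakefield approximate Bayes factor computed from
the estimated effect and its standard error under a Normal(0, prior_sd^2)
effect prior.  Fine-mapping assumes one causal variant per locus with equal
prior weight on each variant, ranks variants by posterior probability, and
reports the minimal set reaching the coverage target (99% by default).

Colocalization follows the standard five-hypothesis framework: H0 no causal
variant, H1/H2 a causal variant for one trait only, H3 two distinct causal
variants, H4 one shared causal variant.  Per-hypothesis evidence is
accumulated from the per-variant log-ABFs with log-sum-exp arithmetic and
combined with the per-variant priors p1, p2, p12 (defaults 1e-4, 1e-4,
1e-5); a locus colocalizes when PPH4 > 0.75 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "CredibleSet",
    "ColocResult",
    "abf",
    "credible_set",
    "coloc",
    "classify_colocalized",
]

DEFAULT_PRIOR_SD = 0.15
DEFAULT_COVERAGE = 0.99
COLOC_THRESHOLD = 0.75


def abf(
    beta: np.ndarray | float,
    se: np.ndarray | float,
    prior_sd: float = DEFAULT_PRIOR_SD,
) -> np.ndarray | float:
    """Log approximate Bayes factor (association vs null) per variant.

    Wakefield's form with shrinkage r = prior_sd^2 / (prior_sd^2 + se^2):

        log ABF = 0.5 * (log(1 - r) + r * z^2)

    Exact for the normal-normal model (it equals the marginal likelihood
    ratio, which tests verify by quadrature).  Returned on the log scale;
    degenerate priors (prior_sd -> 0) give log ABF -> 0.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if prior_sd < 0:
        raise ValueError("prior_sd must be non-negative")
    r = prior_sd**2 / (prior_sd**2 + se**2)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z * z)
    return float(out) if out.ndim == 0 else out


@dataclass
class CredibleSet:
    """A locus's single-causal-variant fine-mapping result.

    ``table`` rows are posterior-descending (ties by ascending position)
    with columns snp, pos, log_abf, posterior, cumulative, in_credible_set.
    """

    locus_id: str
    table: pd.DataFrame
    coverage: float
    size: int

    @property
    def snvs(self) -> List[str]:
        return self.table.loc[self.table["in_credible_set"], "snp"].tolist()


def credible_set(
    locus: pd.DataFrame,
    prior_sd: float = DEFAULT_PRIOR_SD,
    coverage: float = DEFAULT_COVERAGE,
    locus_id: str = "locus",
) -> CredibleSet:
    """Posterior-ranked credible set for one locus.

    ``locus`` needs columns SNP, POS, BETA, SE (any extra columns are
    ignored).  With equal per-variant causal priors the posterior is the
    normalized ABF; the credible set is the minimal posterior-descending
    prefix with cumulative mass >= ``coverage`` (at least one causal
    variant is assumed, so the top variant is always included).
    """
    if locus.empty:
        raise ValueError("locus has no variants")
    lbf = abf(locus["BETA"].to_numpy(float), locus["SE"].to_numpy(float),
              prior_sd)
    lbf = np.atleast_1d(lbf)
    post = np.exp(lbf - logsumexp(lbf))
    df = pd.DataFrame(
        {
            "snp": locus["SNP"].to_numpy(),
            "pos": locus["POS"].to_numpy(),
            "log_abf": lbf,
            "posterior": post,
        }
    ).sort_values(["posterior", "pos"], ascending=[False, True],
                  kind="mergesort").reset_index(drop=True)
    cum = df["posterior"].cumsum()
    size = int(np.searchsorted(cum.to_numpy(), coverage - 1e-12) + 1)
    size = min(size, len(df))
    df["cumulative"] = cum
    df["in_credible_set"] = np.arange(len(df)) < size
    return CredibleSet(locus_id=locus_id, table=df, coverage=coverage,
                       size=size)


@dataclass
class ColocResult:
    """Five-hypothesis colocalization posterior for one locus."""

    locus_id: str
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    priors: Dict[str, float]
    n_snvs: int
    colocalized: bool = False

    def as_dict(self) -> Dict[str, float]:
        return {"PPH0": self.pph0, "PPH1": self.pph1, "PPH2": self.pph2,
                "PPH3": self.pph3, "PPH4": self.pph4}


def coloc(
    locus_x: pd.DataFrame,
    locus_y: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd: float = DEFAULT_PRIOR_SD,
    locus_id: str = "locus",
) -> ColocResult:
    """Two-trait colocalization posterior at a locus.

    Both frames need SNP, BETA, SE columns; only the shared variants are
    used (>= 2 required).  With per-variant log-ABFs l1, l2 the hypothesis
    evidence is, in log space,

        H0: 0
        H1: log p1  + LSE(l1)
        H2: log p2  + LSE(l2)
        H3: log p1 p2 + log( exp(LSE(l1)+LSE(l2)) - exp(LSE(l1+l2)) )
        H4: log p12 + LSE(l1 + l2)

    (LSE = log-sum-exp; the H3 subtraction removes same-variant pairs) and
    the posteriors are the normalized evidences.
    """
    merged = pd.merge(
        locus_x[["SNP", "BETA", "SE"]], locus_y[["SNP", "BETA", "SE"]],
        on="SNP", suffixes=("_x", "_y"),
    )
    n = len(merged)
    if n < 2:
        raise ValueError("coloc needs >= 2 shared variants at the locus")
    l1 = np.atleast_1d(abf(merged["BETA_x"].to_numpy(float),
                           merged["SE_x"].to_numpy(float), prior_sd))
    l2 = np.atleast_1d(abf(merged["BETA_y"].to_numpy(float),
                           merged["SE_y"].to_numpy(float), prior_sd))
    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)
    # log(exp(a) - exp(b)) with a = lse1+lse2 >= b = lse12 up to float noise
    a, b = lse1 + lse2, lse12
    if a <= b:
        lh3_sum = -np.inf
    else:
        lh3_sum = a + np.log1p(-np.exp(b - a))
    lh = np.array(
        [
            0.0,
            np.log(p1) + lse1,
            np.log(p2) + lse2,
            np.log(p1) + np.log(p2) + lh3_sum,
            np.log(p12) + lse12,
        ]
    )
    post = np.exp(lh - logsumexp(lh))
    res = ColocResult(
        locus_id=locus_id,
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        priors={"p1": p1, "p2": p2, "p12": p12},
        n_snvs=n,
    )
    res.colocalized = res.pph4 > COLOC_THRESHOLD
    return res


def classify_colocalized(
    results: Sequence[ColocResult] | pd.DataFrame,
    threshold: float = COLOC_THRESHOLD,
) -> pd.DataFrame:
    """Apply the PPH4 > threshold rule (strict inequality).

    Accepts ColocResult objects or any frame with a ``pph4`` column (e.g. a
    published locus table); returns the frame with a boolean
    ``colocalized`` column.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "pph4" not in df.columns:
            raise ValueError("expected a 'pph4' column")
    else:
        df = pd.DataFrame(
            [{"locus_id": r.locus_id, **{k.lower(): v
                                         for k, v in r.as_dict().items()}}
             for r in results]
        )
        if df.empty:
            df = pd.DataFrame(columns=["locus_id", "pph4", "colocalized"])
            return df
    df["colocalized"] = df["pph4"] > threshold
    return df
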