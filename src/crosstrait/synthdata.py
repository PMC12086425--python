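"""Synthetic GWAS summary statistics, LD panels and cohorts with known truth.

The generator implements the standard polygenic model two traits at a time:
within each LD block the observed z-scores are

    z_t = sqrt(N_t) * R @ beta_t + eps_t,      eps_t ~ Normal(0, R)

with cross-trait sampling-noise correlation ``rho_e * n_overlap /
sqrt(N1*N2)`` induced by overlapping samples.  True per-SNV effects are drawn
so that the requested heritabilities and genetic correlation hold in
expectation, and every quantity a downstream recovery test needs (causal
sets, realized per-block genetic covariance, realized rg, the overlap
intercept) is recorded in a :class:`TruthRecord`.

The cohort simulator produces individual-level data for one-sample MR:
instrument genotypes, a rank-inverse-normal-transformed exposure, a
continuous outcome linked to the exposure by a configurable dose-response
(linear / quadratic / threshold / null, optionally stratum-specific), a
shared confounder, and generic adjustment covariates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ArchitectureConfig, CohortConfig
from .ldpanel import LDPanel
from .sumstats import SumStats

__all__ = [
    "TruthRecord",
    "Cohort",
    "make_ld_panel",
    "simulate_sumstats",
    "simulate_cohort",
    "simulate_instrument_betas",
    "rint",
]


# --------------------------------------------------------------------------
# LD panel
# --------------------------------------------------------------------------

# real genomes mix tight and loose LD neighbourhoods; cycling the decay
# across blocks spreads the LD scores, which is what identifies the LDSC
# intercept separately from the slope
_DECAY_CYCLE = (1.0, 0.0, 2.0 / 3.0, 1.0 / 3.0)


def make_ld_panel(cfg: ArchitectureConfig) -> LDPanel:
    """Build a block-diagonal AR(1) LD panel from an architecture config.

    Block ``b`` has correlation ``rho_b**|i-j|`` with ``rho_b = ld_decay``
    scaled by a fixed heterogeneity cycle (1, 0, 2/3, 1/3), so block 0
    carries exactly ``ld_decay`` and the panel is the identity in the
    ``ld_decay -> 0`` independence limit; AR(1) correlation matrices are
    positive definite for ``|rho| < 1``.  Blocks are laid out in ascending
    (chromosome, position) order with ``snv_spacing`` bp between adjacent
    SNVs, so panel order equals coordinate-sorted order.
    """
    cfg.validate()
    m = cfg.block_size
    lags = np.abs(np.subtract.outer(np.arange(m), np.arange(m)))

    blocks, ids, chroms, poss = [], [], [], []
    chr_offset: Dict[int, int] = {}
    gid = 0
    for b in range(cfg.n_blocks):
        rho = cfg.ld_decay * _DECAY_CYCLE[b % len(_DECAY_CYCLE)]
        R = np.eye(m) if rho == 0.0 else rho ** lags
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > -1e-10, "AR(1) block must be PSD"
        # chromosome index non-decreasing in b keeps panel order sorted
        chrom = (b * 22) // cfg.n_blocks + 1
        start = chr_offset.get(chrom, 0)
        pos = start + cfg.snv_spacing * (1 + np.arange(m))
        chr_offset[chrom] = int(pos[-1])
        blocks.append(R)
        ids.append(np.array([f"rs{100000 + gid + j}" for j in range(m)],
                            dtype=object))
        chroms.append(np.full(m, chrom, dtype=int))
        poss.append(pos.astype(int))
        gid += m
    return LDPanel(blocks=blocks, snv_ids=ids, chrom=chroms, pos=poss)


# --------------------------------------------------------------------------
# Summary statistics
# --------------------------------------------------------------------------

@dataclass
class TruthRecord:
    """Ground truth of a simulated GWAS pair, for recovery tests."""

    causal_1: List[str]
    causal_2: List[str]
    shared: List[str]
    h2_1: float
    h2_2: float
    rg_target: float
    rg_realized: float
    gencov_realized: float
    local_gencov: List[float]        # realized per-block genetic covariance
    cross_intercept: float           # rho_e * n_overlap / sqrt(n1*n2)
    effect_corr_shared: float        # effect-size correlation at shared SNVs
    betas_1: Dict[str, float] = field(default_factory=dict)
    betas_2: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            k: (list(v) if isinstance(v, (list, np.ndarray)) else v)
            for k, v in self.__dict__.items()
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        return cls(**json.loads(Path(path).read_text()))


def _pick_causal(
    rng: np.random.Generator, cfg: ArchitectureConfig, m_causal: int,
    forced: np.ndarray,
) -> np.ndarray:
    """Indices of causal SNVs including the forced (shared) set."""
    M = cfg.M
    if cfg.causal_placement == "spread":
        # evenly spaced over the genome; forced indices appended
        extra = m_causal - forced.size
        if extra <= 0:
            return forced.copy()
        candidates = np.linspace(0, M - 1, extra, dtype=int)
        candidates = np.setdiff1d(candidates, forced)
        return np.sort(np.concatenate([forced, candidates]))
    pool = np.setdiff1d(np.arange(M), forced)
    extra = m_causal - forced.size
    chosen = rng.choice(pool, size=max(extra, 0), replace=False)
    return np.sort(np.concatenate([forced, chosen]))


def simulate_sumstats(
    cfg: ArchitectureConfig, panel: LDPanel
) -> Tuple[SumStats, SumStats, TruthRecord]:
    """Draw a pair of GWAS summary-statistic sets from the polygenic model."""
    cfg.validate()
    if panel.n_snvs != cfg.M:
        raise ValueError("panel was not generated from this config (M differs)")
    rng = np.random.default_rng(cfg.seed)
    M = cfg.M

    m1 = int(round(cfg.prop_causal_1 * M)) if cfg.h2_1 > 0 else 0
    m2 = int(round(cfg.prop_causal_2 * M)) if cfg.h2_2 > 0 else 0
    if cfg.h2_1 > 0 and m1 == 0:
        raise ValueError("h2_1 > 0 requires a non-empty causal set")
    if cfg.h2_2 > 0 and m2 == 0:
        raise ValueError("h2_2 > 0 requires a non-empty causal set")
    for h2, m_c in ((cfg.h2_1, m1), (cfg.h2_2, m2)):
        if m_c and h2 / m_c >= 1.0:
            raise ValueError(
                "per-causal-SNV heritability implies negative residual variance"
            )

    n_shared = int(round(cfg.prop_shared * M))
    n_shared = min(n_shared, m1, m2)
    if n_shared > 0:
        rho_b = cfg.rg * np.sqrt(m1 * m2) / n_shared
        if abs(rho_b) > 1.0:
            raise ValueError(
                f"requested rg={cfg.rg} unattainable with {n_shared} shared "
                f"causal SNVs (needs effect correlation {rho_b:.3f})"
            )
    else:
        rho_b = 0.0  # rg parameter ignored when nothing is shared

    if cfg.shared_blocks is not None and n_shared > 0:
        pool = np.concatenate(
            [np.arange(b * cfg.block_size, (b + 1) * cfg.block_size)
             for b in cfg.shared_blocks]
        )
    else:
        pool = np.arange(M)
    shared_idx = np.sort(rng.choice(pool, size=n_shared, replace=False))
    causal_1 = _pick_causal(rng, cfg, m1, shared_idx) if m1 else np.array([], int)
    causal_2 = _pick_causal(rng, cfg, m2, shared_idx) if m2 else np.array([], int)

    # --- effect sizes ------------------------------------------------------
    b1 = np.zeros(M)
    b2 = np.zeros(M)
    s1 = np.sqrt(cfg.h2_1 / m1) if m1 else 0.0
    s2 = np.sqrt(cfg.h2_2 / m2) if m2 else 0.0
    if cfg.effect_dist == "normal":
        b1[causal_1] = rng.normal(0.0, s1, size=causal_1.size)
        b2[causal_2] = rng.normal(0.0, s2, size=causal_2.size)
        if n_shared:
            x = rng.normal(size=n_shared)
            y = rho_b * x + np.sqrt(max(0.0, 1 - rho_b**2)) * rng.normal(
                size=n_shared)
            b1[shared_idx] = s1 * x
            b2[shared_idx] = s2 * y
    else:  # fixed magnitudes, random signs
        b1[causal_1] = s1 * rng.choice([-1.0, 1.0], size=causal_1.size)
        b2[causal_2] = s2 * rng.choice([-1.0, 1.0], size=causal_2.size)
        if n_shared:
            sign1 = rng.choice([-1.0, 1.0], size=n_shared)
            agree = rng.random(n_shared) < (1.0 + rho_b) / 2.0
            b1[shared_idx] = s1 * sign1
            b2[shared_idx] = s2 * np.where(agree, sign1, -sign1)

    # --- z-scores block by block ------------------------------------------
    c = cfg.rho_e * cfg.n_overlap / np.sqrt(cfg.n1 * cfg.n2)
    z1 = np.empty(M)
    z2 = np.empty(M)
    local_cov = []
    offset = 0
    chol_cache: Dict[int, np.ndarray] = {}
    for b, R in enumerate(panel.blocks):
        m = R.shape[0]
        key = (m, float(R[0, 1]) if m > 1 else 0.0)
        L = chol_cache.get(key)
        if L is None:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
            chol_cache[key] = L
        sl = slice(offset, offset + m)
        mean1 = np.sqrt(cfg.n1) * R @ b1[sl]
        mean2 = np.sqrt(cfg.n2) * R @ b2[sl]
        x = rng.standard_normal(m)
        y = rng.standard_normal(m)
        e1 = L @ x
        e2 = L @ (c * x + np.sqrt(max(0.0, 1 - c * c)) * y)
        z1[sl] = mean1 + e1
        z2[sl] = mean2 + e2
        local_cov.append(float(b1[sl] @ b2[sl]))
        offset += m

    snv_ids = np.concatenate(panel.snv_ids)
    chrom = np.concatenate(panel.chrom)
    pos = np.concatenate(panel.pos)
    eaf = rng.uniform(0.05, 0.95, size=M)
    ea = np.where(rng.random(M) < 0.5, "A", "C")
    oa = np.where(ea == "A", "G", "T")

    def _to_sumstats(z: np.ndarray, n: int, label: str) -> SumStats:
        se = np.full(M, 1.0 / np.sqrt(n))
        beta = z * se
        p = np.maximum(2.0 * stats.norm.sf(np.abs(z)), 5e-324)
        df = pd.DataFrame(
            {
                "SNP": snv_ids,
                "CHR": chrom,
                "POS": pos,
                "EA": ea,
                "OA": oa,
                "EAF": eaf,
                "BETA": beta,
                "SE": se,
                "P": p,
                "N": n,
            }
        )
        return SumStats(trait=label, df=df, metadata={"N": n, "source": "simulated"})

    ss1 = _to_sumstats(z1, cfg.n1, "trait1")
    ss2 = _to_sumstats(z2, cfg.n2, "trait2")

    gencov = float(b1 @ b2)
    denom = np.sqrt((b1 @ b1) * (b2 @ b2))
    truth = TruthRecord(
        causal_1=[str(s) for s in snv_ids[causal_1]],
        causal_2=[str(s) for s in snv_ids[causal_2]],
        shared=[str(s) for s in snv_ids[shared_idx]],
        h2_1=cfg.h2_1,
        h2_2=cfg.h2_2,
        rg_target=cfg.rg if n_shared else 0.0,
        rg_realized=float(gencov / denom) if denom > 0 else 0.0,
        gencov_realized=gencov,
        local_gencov=local_cov,
        cross_intercept=float(c),
        effect_corr_shared=float(rho_b),
        betas_1={str(snv_ids[j]): float(b1[j]) for j in causal_1},
        betas_2={str(snv_ids[j]): float(b2[j]) for j in causal_2},
    )
    return ss1, ss2, truth


# --------------------------------------------------------------------------
# Cohort
# --------------------------------------------------------------------------

def rint(x: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offsets, average ties)."""
    x = np.asarray(x, dtype=float)
    r = stats.rankdata(x, method="average")
    return stats.norm.ppf((r - 0.375) / (x.size + 0.25))


@dataclass
class Cohort:
    """Individual-level data for one-sample MR.

    ``data`` holds exposure, outcome and covariates (one row per person);
    ``genotypes`` is the n x n_snvs dose matrix for the instrument SNVs,
    oriented to the generator's effect allele; ``snv_effects`` are the true
    per-allele exposure effects (positive orientation not assumed).
    """

    data: pd.DataFrame
    genotypes: np.ndarray
    snv_ids: List[str]
    eafs: np.ndarray
    snv_effects: np.ndarray
    config: CohortConfig

    @property
    def n(self) -> int:
        return len(self.data)

    def covariate_columns(self) -> List[str]:
        skip = {"exposure", "outcome"}
        return [c for c in self.data.columns if c not in skip]

    def write(self, path: str | Path) -> None:
        """Delimited table: phenotype/covariate columns then genotype doses."""
        geno = pd.DataFrame(self.genotypes, columns=self.snv_ids,
                            index=self.data.index)
        pd.concat([self.data, geno], axis=1).to_csv(path, sep="\t", index=False)

    def write_vcf(self, path: str | Path) -> None:
        """Minimal VCF 4.2 export of the instrument genotypes."""
        lines = ["##fileformat=VCFv4.2",
                 "##source=crosstrait-synthetic-cohort",
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 + "".join(f"\tP{i}" for i in range(self.n))]
        codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, sid in enumerate(self.snv_ids):
            gts = "\t".join(codes[int(g)] for g in self.genotypes[:, j])
            lines.append(f"1\t{1000 + j}\t{sid}\tA\tG\t.\tPASS\t.\tGT\t{gts}")
        Path(path).write_text("\n".join(lines) + "\n")


def _subgroup_slope(cfg: CohortConfig, data: pd.DataFrame) -> np.ndarray:
    """Per-person additional linear causal slope from subgroup_effects."""
    slope = np.zeros(len(data))
    if not cfg.subgroup_effects:
        return slope
    for dim, mapping in cfg.subgroup_effects.items():
        if dim == "sex":
            labels = np.where(data["sex"].to_numpy() == 1, "male", "female")
        elif dim == "age_band":
            labels = np.where(data["age"].to_numpy() >= 65,
                              "age_ge_65", "age_lt_65")
        elif dim == "menopause":
            post = data["postmenopausal"].to_numpy() == 1
            female = data["sex"].to_numpy() == 0
            labels = np.where(post & female, "postmenopausal",
                              np.where(female, "premenopausal", "_none"))
        else:  # pragma: no cover - blocked by validate()
            raise ValueError(dim)
        for lab, val in mapping.items():
            slope[labels == lab] += val
    return slope


def simulate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate an individual-level cohort with known causal structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n, cfg.n_snvs

    eafs = (np.asarray(cfg.eafs, dtype=float) if cfg.eafs is not None
            else rng.uniform(0.1, 0.9, size=k))
    if cfg.per_snv_effects is not None:
        effects = np.asarray(cfg.per_snv_effects, dtype=float)
    else:
        # ~6% exposure variance explained across the instruments, matching
        # the variance the study's 143 index SNVs capture
        target_r2 = 0.059
        var_g = np.sum(2.0 * eafs * (1.0 - eafs))
        effects = np.full(k, np.sqrt(target_r2 / var_g))

    genotypes = rng.binomial(2, eafs, size=(n, k)).astype(float)

    age = rng.integers(40, 71, size=n).astype(float)
    sex = rng.integers(0, 2, size=n).astype(float)      # 1 = male
    bmi = rng.normal(27.0, 4.0, size=n)
    center = rng.integers(0, cfg.n_centers, size=n).astype(float)
    month = rng.integers(0, 12, size=n).astype(float)
    supplement = (rng.random(n) < 0.2).astype(float)
    p_post = stats.norm.cdf((age - 51.0) / 3.0)
    postmenopausal = ((sex == 0) & (rng.random(n) < p_post)).astype(float)
    pcs = rng.normal(size=(n, cfg.n_pcs))

    confounder = rng.standard_normal(n)
    cov_x = (-0.01 * (age - 55.0) - 0.10 * sex - 0.02 * (bmi - 27.0)
             + 0.30 * np.sin(2 * np.pi * month / 12.0) + 0.40 * supplement
             + pcs @ np.full(cfg.n_pcs, 0.02))
    genetic = (genotypes - 2.0 * eafs) @ effects
    x_lin = (genetic + cfg.confounder_effect_x * confounder + cov_x
             + cfg.noise_sd_x * rng.standard_normal(n))
    exposure = rint(x_lin)

    data = pd.DataFrame(
        {
            "exposure": exposure,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "center": center,
            "month": month,
            "supplement": supplement,
            "postmenopausal": postmenopausal,
        }
    )
    for i in range(cfg.n_pcs):
        data[f"pc{i + 1}"] = pcs[:, i]

    cov_y = (-0.02 * (age - 55.0) + 0.30 * sex + 0.03 * (bmi - 27.0)
             - 0.20 * postmenopausal + pcs @ np.full(cfg.n_pcs, 0.02))
    slope_extra = _subgroup_slope(cfg, data)
    outcome = (cfg.causal_fn(exposure) + slope_extra * exposure
               + cfg.confounder_effect_y * confounder + cov_y
               + cfg.noise_sd_y * rng.standard_normal(n))
    data.insert(1, "outcome", outcome)

    snv_ids = [f"iv{j + 1:03d}" for j in range(k)]
    return Cohort(data=data, genotypes=genotypes, snv_ids=snv_ids,
                  eafs=eafs, snv_effects=effects, config=cfg)


# --------------------------------------------------------------------------
# Instrument-level generator for two-sample MR experiments
# --------------------------------------------------------------------------

def simulate_instrument_betas(
    n_iv: int = 143,
    beta_causal: float = 0.0,
    n_x: int = 50_000,
    n_y: int = 50_000,
    r2_instruments: float = 0.059,
    pleiotropy_mean: float = 0.0,
    pleiotropy_sd: float = 0.0,
    outlier_idx: Optional[np.ndarray] = None,
    outlier_ratio: float = 0.0,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Harmonized instrument-level effect estimates for two-sample MR.

    True instrument effects are half-normal with total variance explained
    ``r2_instruments``; observed effects add sampling noise at 1/sqrt(N).
    Directional pleiotropy enters through a per-IV intercept with mean
    ``pleiotropy_mean``; ``outlier_idx`` IVs get outcome effects at
    ``outlier_ratio`` times the causal ratio (planted PRESSO outliers).
    """
    rng = np.random.default_rng(seed)
    bx_true = np.abs(rng.normal(0.0, np.sqrt(r2_instruments / n_iv), n_iv))
    se_x = np.full(n_iv, 1.0 / np.sqrt(n_x))
    se_y = np.full(n_iv, 1.0 / np.sqrt(n_y))
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, n_iv)
    by_true = beta_causal * bx_true + alpha
    if outlier_idx is not None:
        by_true = by_true.copy()
        if isinstance(outlier_idx, str) and outlier_idx == "strongest":
            outlier_idx = np.array([int(np.argmax(bx_true))])
        by_true[outlier_idx] = outlier_ratio * beta_causal * bx_true[outlier_idx]
    bx = bx_true + rng.normal(0.0, se_x)
    by = by_true + rng.normal(0.0, se_y)
    return {
        "beta_x": bx, "se_x": se_x, "beta_y": by, "se_y": se_y,
        "beta_x_true": bx_true, "beta_y_true": by_true,
    }
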