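"""Configuration objects for the synthetic generators and the pipeline.

Defaults emulate the data structure of a UK-Biobank-scale cross-trait study of
serum 25-hydroxyvitamin D (exposure, GWAS N = 417,580) and estimated heel bone
mineral density (outcome, GWAS N = 426,824): two overlapping-sample
quantitative-trait GWASs with block LD and a polygenic architecture, and an
individual-level cohort carrying the instrument genotypes, a rank-normalized
exposure, a continuous outcome and the usual adjustment covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["ArchitectureConfig", "CohortConfig", "CausalFunction"]

_CAUSAL_FN_LABELS = ("linear", "quadratic", "threshold", "null")
_SUBGROUP_DIMS = {
    "sex": ("male", "female"),
    "age_band": ("age_lt_65", "age_ge_65"),
    "menopause": ("premenopausal", "postmenopausal"),
}


@dataclass
class ArchitectureConfig:
    """Generative model for a pair of GWAS summary-statistic sets.

    Heritabilities default to the exposure/outcome estimates (0.10 and 0.27)
    the study design targets; sample sizes default to the source GWAS sizes.
    ``M = n_blocks * block_size`` SNVs live on independent LD blocks with
    AR(1) correlation ``ld_decay**|i-j|`` inside each block.
    """

    n1: int = 417_580
    n2: int = 426_824
    n_overlap: int = 300_000
    n_blocks: int = 100
    block_size: int = 50
    h2_1: float = 0.10
    h2_2: float = 0.27
    rg: float = 0.0
    rho_e: float = 0.05
    ld_decay: float = 0.8
    prop_causal_1: float = 0.10
    prop_causal_2: float = 0.10
    prop_shared: float = 0.02
    seed: int = 0
    # SNV spacing in base pairs; blocks are laid out contiguously per
    # chromosome so distance windows behave like real coordinates.
    snv_spacing: int = 5_000
    # "normal": effect sizes i.i.d. normal within the causal set.
    # "fixed": equal magnitude sqrt(h2/m) with random sign (guaranteed
    # detectable hits for instrument-recovery experiments).
    effect_dist: str = "normal"
    # "random": causal SNVs drawn uniformly; "spread": evenly spaced across
    # blocks so planted hits are LD-independent.
    causal_placement: str = "random"
    # Confine the shared (pleiotropic) causal SNVs to these block indices;
    # None means anywhere in the intersection of the causal sets.
    shared_blocks: Optional[Sequence[int]] = None

    @property
    def M(self) -> int:
        return self.n_blocks * self.block_size

    def validate(self) -> None:
        if not (0.0 <= self.h2_1 <= 1.0 and 0.0 <= self.h2_2 <= 1.0):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not (-1.0 <= self.rg <= 1.0):
            raise ValueError("rg must lie in [-1, 1]")
        if not (-1.0 <= self.rho_e <= 1.0):
            raise ValueError("rho_e must lie in [-1, 1]")
        if self.n_overlap > min(self.n1, self.n2):
            raise ValueError("n_overlap cannot exceed min(n1, n2)")
        if self.n_overlap < 0:
            raise ValueError("n_overlap must be non-negative")
        for name in ("prop_causal_1", "prop_causal_2", "prop_shared"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("n_blocks and block_size must be positive")
        if self.effect_dist not in ("normal", "fixed"):
            raise ValueError("effect_dist must be 'normal' or 'fixed'")
        if self.causal_placement not in ("random", "spread"):
            raise ValueError("causal_placement must be 'random' or 'spread'")
        if self.shared_blocks is not None:
            bad = [b for b in self.shared_blocks if not 0 <= b < self.n_blocks]
            if bad:
                raise ValueError(f"shared_blocks out of range: {bad}")


@dataclass
class CausalFunction:
    """Exposure->outcome dose-response used by the cohort simulator.

    ``label`` is one of linear / quadratic / threshold / null.  The quadratic
    form is ``slope*x + quad*x**2``; the threshold form applies ``slope``
    above ``threshold`` and ``slope_below`` underneath.
    """

    label: str = "null"
    slope: float = 0.0
    quad: float = 0.0
    threshold: float = 0.0
    slope_below: float = 0.0

    def validate(self) -> None:
        if self.label not in _CAUSAL_FN_LABELS:
            raise ValueError(
                f"causal_fn label {self.label!r} not in {_CAUSAL_FN_LABELS}"
            )

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.label == "null":
            return np.zeros_like(x)
        if self.label == "linear":
            return self.slope * x
        if self.label == "quadratic":
            return self.slope * x + self.quad * x * x
        if self.label == "threshold":
            return np.where(
                x >= self.threshold,
                self.slope * (x - self.threshold),
                self.slope_below * (x - self.threshold),
            )
        raise ValueError(self.label)


@dataclass
class CohortConfig:
    """Individual-level cohort emulating the one-sample MR analysis sample.

    143 instrument SNVs by default (the exposure GWAS's index-SNV count);
    per-SNV allele effects default to a ~6% exposure variance explained,
    matching the variance the study's instruments capture.  A single
    standard-normal confounder loads on both exposure and outcome so naive
    OLS is biased while IV estimation is consistent.
    """

    n: int = 10_000
    n_snvs: int = 143
    eafs: Optional[np.ndarray] = None
    per_snv_effects: Optional[np.ndarray] = None
    causal_fn: CausalFunction = field(default_factory=CausalFunction)
    # dimension -> {stratum label: causal slope}; overrides causal_fn's
    # linear slope additively across dimensions for stratum members.
    subgroup_effects: Optional[dict] = None
    confounder_effect_x: float = 0.3
    confounder_effect_y: float = 0.3
    noise_sd_x: float = 0.95
    noise_sd_y: float = 0.95
    n_pcs: int = 10
    n_centers: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1 or self.n_snvs < 1:
            raise ValueError("n and n_snvs must be positive")
        self.causal_fn.validate()
        if self.eafs is not None:
            eafs = np.asarray(self.eafs, dtype=float)
            if eafs.shape != (self.n_snvs,):
                raise ValueError("eafs must have length n_snvs")
            if np.any(eafs <= 0.0) or np.any(eafs >= 1.0):
                raise ValueError("eafs must lie strictly in (0, 1)")
        if self.per_snv_effects is not None:
            eff = np.asarray(self.per_snv_effects, dtype=float)
            if eff.shape != (self.n_snvs,):
                raise ValueError("per_snv_effects must have length n_snvs")
        if self.subgroup_effects is not None:
            for dim, mapping in self.subgroup_effects.items():
                if dim not in _SUBGROUP_DIMS:
                    raise ValueError(
                        f"unknown subgroup dimension {dim!r}; "
                        f"expected one of {sorted(_SUBGROUP_DIMS)}"
                    )
                bad = [k for k in mapping if k not in _SUBGROUP_DIMS[dim]]
                if bad:
                    raise ValueError(
                        f"subgroup_effects[{dim!r}] references undefined "
                        f"strata {bad}; valid: {_SUBGROUP_DIMS[dim]}"
                    )
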