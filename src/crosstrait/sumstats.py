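"""GWAS summary-statistic containers, I/O, allele harmonization and clumping.

Conventions follow the tools of the field: coordinates are 1-based, clumping
windows are closed +/- kb intervals around the index position (PLINK style),
and harmonization orients every instrument so the exposure effect is
non-negative before MR.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ldpanel import LDPanel

__all__ = [
    "VariantRecord",
    "SumStats",
    "InstrumentSet",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "clump",
    "select_instruments",
    "SumStatsFormatError",
]

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumStatsFormatError(ValueError):
    """Raised for structurally invalid summary-statistic input."""


@dataclass(frozen=True)
class VariantRecord:
    """One GWAS association: identifiers, alleles, effect and uncertainty."""

    snv_id: str
    chr: int
    pos: int
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")
        if self.ea == self.oa:
            raise ValueError("effect and other allele must differ")


@dataclass
class SumStats:
    """A trait's summary statistics: ordered variant table plus metadata."""

    trait: str
    df: pd.DataFrame
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsFormatError(f"missing mandatory column(s): {missing}")
        if self.df["SNP"].duplicated().any():
            dups = self.df.loc[self.df["SNP"].duplicated(), "SNP"].tolist()[:5]
            raise SumStatsFormatError(f"duplicate SNV ids (e.g. {dups})")
        self.df = (self.df.sort_values(["CHR", "POS"], kind="mergesort")
                   .reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        return (self.df["BETA"] / self.df["SE"]).to_numpy()

    def record(self, snv_id: str) -> VariantRecord:
        row = self.df.loc[self.df["SNP"] == snv_id]
        if row.empty:
            raise KeyError(snv_id)
        r = row.iloc[0]
        return VariantRecord(
            snv_id=str(r["SNP"]), chr=int(r["CHR"]), pos=int(r["POS"]),
            ea=str(r["EA"]), oa=str(r["OA"]), eaf=float(r["EAF"]),
            beta=float(r["BETA"]), se=float(r["SE"]), p=float(r["P"]),
            n=int(r["N"]),
        )


def read_sumstats(
    path: str | Path,
    trait: str = "trait",
    dialect: Optional[Dict[str, str]] = None,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistic file.

    ``dialect`` maps canonical column names (SNP, CHR, POS, EA, OA, EAF,
    BETA, SE, P, N) to the file's actual headers.  Malformed rows (se <= 0,
    p outside (0, 1], identical alleles, unparseable numbers) are dropped and
    counted; the drop count is stored in ``metadata['n_dropped']``.
    """
    df = pd.read_csv(path, sep=sep)
    if dialect:
        rename = {v: k for k, v in dialect.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsFormatError(
            f"missing mandatory column(s) {missing} in {path}"
        )
    df = df[REQUIRED_COLUMNS].copy()
    n_in = len(df)
    for col in ("CHR", "POS", "EAF", "BETA", "SE", "P", "N"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    ok = (
        df[REQUIRED_COLUMNS].notna().all(axis=1)
        & (df["SE"] > 0)
        & (df["P"] > 0) & (df["P"] <= 1)
        & (df["EAF"] > 0) & (df["EAF"] < 1)
        & (df["EA"].astype(str) != df["OA"].astype(str))
    )
    dropped = int(n_in - ok.sum())
    if dropped:
        log.warning("%s: dropped %d malformed row(s)", path, dropped)
    df = df.loc[ok].reset_index(drop=True)
    df["CHR"] = df["CHR"].astype(int)
    df["POS"] = df["POS"].astype(int)
    df["N"] = df["N"].astype(int)
    return SumStats(trait=trait, df=df,
                    metadata={"source": str(path), "n_dropped": dropped})


def write_sumstats(ss: SumStats, path: str | Path, sep: str = "\t") -> None:
    ss.df.to_csv(path, sep=sep, index=False)


# --------------------------------------------------------------------------
# Harmonization
# --------------------------------------------------------------------------

@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome effect pairs for MR.

    ``df`` columns: snp, chr, pos, ea, oa, eaf_x, eaf_y, beta_x, se_x,
    beta_y, se_y, n_x, n_y, palindromic, flipped.  All rows are oriented so
    ``beta_x >= 0``.  ``excluded`` records each removed SNV with its reason.
    """

    df: pd.DataFrame
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["snp", "reason"])
    )

    @property
    def n_iv(self) -> int:
        return len(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask: np.ndarray) -> "InstrumentSet":
        return InstrumentSet(df=self.df.loc[mask].reset_index(drop=True),
                             excluded=self.excluded)

    def drop_snvs(self, snv_ids: Iterable[str], reason: str) -> "InstrumentSet":
        snv_ids = set(snv_ids)
        mask = ~self.df["snp"].isin(snv_ids)
        removed = self.df.loc[~mask, ["snp"]].assign(reason=reason)
        return InstrumentSet(
            df=self.df.loc[mask].reset_index(drop=True),
            excluded=pd.concat([self.excluded, removed], ignore_index=True),
        )


def _is_palindromic(ea: str, oa: str) -> bool:
    return (ea, oa) in _PALINDROMIC


def harmonize(
    x: SumStats,
    y: SumStats,
    palindrome_eaf_limit: float = 0.42,
) -> InstrumentSet:
    """Align outcome effects to the exposure's effect allele.

    Rules, in order: direct allele match keeps the outcome beta; swapped
    alleles re-sign it; strand flips (A<->T, C<->G complement) are attempted
    before exclusion; palindromic SNVs are kept only when informative
    (min(EAF, 1-EAF) < ``palindrome_eaf_limit`` in both studies), using EAF
    agreement to fix their orientation; finally both betas are flipped where
    needed so every exposure beta is non-negative.
    """
    shared = pd.merge(x.df, y.df, on="SNP", suffixes=("_x", "_y"))
    if shared.empty:
        raise ValueError("no shared SNV ids between the two traits")

    rows, excluded = [], []
    for r in shared.itertuples(index=False):
        ea_x, oa_x = str(r.EA_x), str(r.OA_x)
        ea_y, oa_y = str(r.EA_y), str(r.OA_y)
        beta_y, eaf_y = float(r.BETA_y), float(r.EAF_y)
        flipped_strand = False

        if (ea_y, oa_y) == (ea_x, oa_x):
            sign = 1.0
        elif (ea_y, oa_y) == (oa_x, ea_x):
            sign = -1.0
        else:
            cea = _COMPLEMENT.get(ea_y)
            coa = _COMPLEMENT.get(oa_y)
            if (cea, coa) == (ea_x, oa_x):
                sign, flipped_strand = 1.0, True
            elif (cea, coa) == (oa_x, ea_x):
                sign, flipped_strand = -1.0, True
            else:
                excluded.append((r.SNP, "allele_mismatch"))
                continue

        palindromic = _is_palindromic(ea_x, oa_x)
        if palindromic:
            eaf_x = float(r.EAF_x)
            if (min(eaf_x, 1 - eaf_x) >= palindrome_eaf_limit
                    or min(eaf_y, 1 - eaf_y) >= palindrome_eaf_limit):
                excluded.append((r.SNP, "palindromic_ambiguous"))
                continue
            # orientation by frequency agreement: if the outcome frequency
            # matches the exposure's minor/major side after the sign rule,
            # keep; otherwise the strands disagree -> flip the sign
            eaf_aligned = eaf_y if sign > 0 else 1 - eaf_y
            if (eaf_x < 0.5) != (eaf_aligned < 0.5):
                sign = -sign

        beta_y_aligned = sign * beta_y
        eaf_y_aligned = eaf_y if sign > 0 else 1 - eaf_y
        beta_x = float(r.BETA_x)
        eaf_x = float(r.EAF_x)
        ea, oa = ea_x, oa_x
        orient_flip = beta_x < 0
        if orient_flip:
            beta_x, beta_y_aligned = -beta_x, -beta_y_aligned
            eaf_x, eaf_y_aligned = 1 - eaf_x, 1 - eaf_y_aligned
            ea, oa = oa, ea
        rows.append(
            {
                "snp": r.SNP, "chr": int(r.CHR_x), "pos": int(r.POS_x),
                "ea": ea, "oa": oa,
                "eaf_x": eaf_x, "eaf_y": eaf_y_aligned,
                "beta_x": beta_x, "se_x": float(r.SE_x),
                "beta_y": beta_y_aligned, "se_y": float(r.SE_y),
                "n_x": int(r.N_x), "n_y": int(r.N_y),
                "palindromic": palindromic,
                "flipped": bool(orient_flip or flipped_strand or sign < 0),
            }
        )
    df = pd.DataFrame(rows)
    exc = pd.DataFrame(excluded, columns=["snp", "reason"])
    return InstrumentSet(df=df, excluded=exc)


# --------------------------------------------------------------------------
# Clumping and instrument selection
# --------------------------------------------------------------------------

def clump(
    s: SumStats,
    panel: LDPanel,
    p1: float = 5e-8,
    p2: float = 1e-5,
    r2: float = 0.2,
    kb: float = 500.0,
) -> pd.DataFrame:
    """Greedy PLINK-style clumping.

    Repeatedly takes the smallest-p remaining SNV with p < p1 as an index
    (p ties broken by ascending (chr, pos)) and assigns to it every remaining
    SNV with p < p2 within +/- kb kilobases *and* LD r^2 > r2.  SNV pairs not
    covered by the panel are treated as LD-free with a warning.  Returns one
    row per index, sorted by p: columns index_snp, chr, pos, p, n_assigned,
    assigned (semicolon-joined ids).
    """
    df = s.df
    cand = df.loc[df["P"] < p1, ["SNP", "CHR", "POS", "P"]]
    if cand.empty:
        return pd.DataFrame(
            columns=["index_snp", "chr", "pos", "p", "n_assigned", "assigned"]
        )
    secondary = df.loc[df["P"] < p2, ["SNP", "CHR", "POS", "P"]]
    secondary = secondary.sort_values(
        ["P", "CHR", "POS"], kind="mergesort").reset_index(drop=True)

    uncovered_warned = False
    alive = dict.fromkeys(secondary["SNP"].tolist(), True)
    info = {r.SNP: (int(r.CHR), int(r.POS), float(r.P))
            for r in secondary.itertuples(index=False)}
    order = secondary["SNP"].tolist()
    index_rows = []
    for snp in order:
        if not alive.get(snp, False):
            continue
        chrom, pos, p = info[snp]
        if p >= p1:
            continue
        alive[snp] = False
        assigned = []
        half_window = kb * 1000.0
        loc_idx = panel.locate(str(snp))
        for other in order:
            if not alive.get(other, False):
                continue
            ochr, opos, _ = info[other]
            if ochr != chrom or abs(opos - pos) > half_window:
                continue
            if loc_idx is None or panel.locate(str(other)) is None:
                if not uncovered_warned:
                    log.warning(
                        "clump: SNV pair(s) uncovered by the LD panel; "
                        "treated as r^2=0"
                    )
                    uncovered_warned = True
                continue
            r2_obs = panel.r2(str(snp), str(other))
            if r2_obs is not None and r2_obs > r2:
                alive[other] = False
                assigned.append(other)
        index_rows.append(
            {
                "index_snp": snp, "chr": chrom, "pos": pos, "p": p,
                "n_assigned": len(assigned),
                "assigned": ";".join(assigned),
            }
        )
    out = pd.DataFrame(index_rows).sort_values(
        ["p", "chr", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def select_instruments(
    s: SumStats,
    panel: LDPanel,
    p_thresh: float = 5e-8,
    window_mb: float = 10.0,
    r2: float = 0.01,
) -> pd.DataFrame:
    """Index-SNV selection for MR instruments.

    Distance-based clumping over a +/- ``window_mb`` Mb window with an LD
    r^2 threshold (defaults: 10 Mb, r^2 < 0.01, p < 5e-8), i.e. :func:`clump`
    with p2 = p1.
    """
    return clump(s, panel, p1=p_thresh, p2=p_thresh, r2=r2,
                 kb=window_mb * 1000.0)
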