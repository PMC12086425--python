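"""End-to-end orchestration of the cross-trait analysis stages.

Stage order mirrors the study design: simulate (or load) the two GWASs and
the cohort, harmonize and clump, global and local genetic correlation,
two-sample MR, one-sample MR, the pleiotropy scan, fine-mapping and
colocalization.  Every stage draws its seed deterministically from the
master seed plus the stage name, writes its tables under the output
directory, and is recorded in a JSON run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coloc import coloc, credible_set
from .config import ArchitectureConfig, CausalFunction, CohortConfig
from .ldsc import ld_scores, ldsc_rg, local_gencov_scan
from .mr1 import build_prs, nonlinear_mr, subgroup_mr, wald_iv
from .mr2 import egger, ivw, leave_one_out, mr_presso, steiger_filter, weighted_median
from .pleio import estimate_null_corr, null_stat_draws, pleio_scan
from .published import apply_coloc_rule, apply_significance_filter, load_published_hits
from .sumstats import harmonize, select_instruments, write_sumstats
from .synthdata import make_ld_panel, simulate_cohort, simulate_sumstats

__all__ = ["RunConfig", "run", "stage_seed", "ALL_STAGES"]

ALL_STAGES = ["simulate", "harmonize", "ldsc", "localscan", "mr2s", "mr1s",
              "pleio", "finemap", "coloc", "report"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(master_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Structured configuration for a full pipeline run."""

    out_dir: str = "results/run"
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    architecture: Dict = field(default_factory=dict)
    cohort: Dict = field(default_factory=dict)
    alpha: float = 0.05
    pleio_p1: float = 5e-8
    pleio_p2: float = 1e-5
    instrument_p: float = 5e-8
    n_mc_draws: int = 200_000

    def validate(self) -> None:
        for name in ("alpha", "pleio_p1", "pleio_p2", "instrument_p"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**payload)
        cfg.validate()
        return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig) -> Dict:
    """Execute the requested stages in dependency order; returns the manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {"version": __version__, "seed": config.seed,
                      "stages": [], "outputs": {}}
    state: Dict = {}

    def record(stage: str, files: List[Path]) -> None:
        manifest["stages"].append(stage)
        manifest["outputs"][stage] = {
            str(f.relative_to(out)): _digest(f) for f in files
        }

    def require(stage: str, key: str):
        if key not in state:
            raise RuntimeError(
                f"stage '{stage}' requires missing output of an earlier "
                f"stage (need '{key}'; did 'simulate' run?)"
            )
        return state[key]

    for stage in [s for s in ALL_STAGES if s in config.stages]:
        seed = stage_seed(config.seed, stage)
        if stage == "simulate":
            arch = ArchitectureConfig(**{**config.architecture, "seed": seed})
            panel = make_ld_panel(arch)
            ss1, ss2, truth = simulate_sumstats(arch, panel)
            ccfg_kwargs = dict(config.cohort)
            causal = ccfg_kwargs.pop("causal_fn", None)
            if isinstance(causal, dict):
                ccfg_kwargs["causal_fn"] = CausalFunction(**causal)
            cohort = simulate_cohort(CohortConfig(**{**ccfg_kwargs,
                                                     "seed": seed + 1}))
            f1, f2 = out / "sumstats_exposure.tsv", out / "sumstats_outcome.tsv"
            write_sumstats(ss1, f1)
            write_sumstats(ss2, f2)
            ft = out / "truth.json"
            truth.to_json(ft)
            fc = out / "cohort.tsv"
            cohort.write(fc)
            state.update(panel=panel, ss1=ss1, ss2=ss2, truth=truth,
                         cohort=cohort, arch=arch)
            record(stage, [f1, f2, ft, fc])
        elif stage == "harmonize":
            ss1 = require(stage, "ss1")
            ss2 = require(stage, "ss2")
            panel = require(stage, "panel")
            hz = harmonize(ss1, ss2)
            instruments = select_instruments(ss1, panel,
                                             p_thresh=config.instrument_p)
            fi = out / "instruments.tsv"
            instruments.to_csv(fi, sep="\t", index=False)
            fh = out / "harmonized.tsv"
            hz.df.to_csv(fh, sep="\t", index=False)
            iv = hz.subset(hz.df["snp"].isin(instruments["index_snp"]).to_numpy())
            state.update(hz=hz, instruments=instruments, iv=iv)
            record(stage, [fh, fi])
        elif stage == "ldsc":
            ss1, ss2 = require(stage, "ss1"), require(stage, "ss2")
            panel = require(stage, "panel")
            ell = ld_scores(panel)
            fit = ldsc_rg(ss1, ss2, ell)
            ff = out / "ldsc.json"
            ff.write_text(json.dumps(dataclasses.asdict(fit)))
            state.update(ell=ell, ldsc_fit=fit)
            record(stage, [ff])
        elif stage == "localscan":
            ss1, ss2 = require(stage, "ss1"), require(stage, "ss2")
            panel = require(stage, "panel")
            fit = require(stage, "ldsc_fit")
            regions = local_gencov_scan(ss1, ss2, panel,
                                        cross_intercept=fit.cross_intercept,
                                        alpha=config.alpha)
            df = pd.DataFrame([dataclasses.asdict(r) for r in regions])
            fr = out / "local_scan.tsv"
            df.to_csv(fr, sep="\t", index=False)
            state["local"] = regions
            record(stage, [fr])
        elif stage == "mr2s":
            iv = require(stage, "iv")
            fits = [ivw(iv), egger(iv), weighted_median(iv, seed=seed),
                    mr_presso(iv, seed=seed)]
            loo = leave_one_out(iv)
            filtered, steiger_report = steiger_filter(iv)
            fits.append(ivw(filtered))
            fits[-1].method = "ivw_steiger_filtered"
            rows = [dataclasses.asdict(f) for f in fits]
            fm = out / "mr_twosample.tsv"
            pd.DataFrame(rows).to_csv(fm, sep="\t", index=False)
            fs = out / "mr_sensitivity.json"
            fs.write_text(json.dumps({
                "leave_one_out": [dataclasses.asdict(f) for f in loo],
                "steiger_removed": steiger_report,
            }, default=str))
            state["mr2s"] = fits
            record(stage, [fm, fs])
        elif stage == "mr1s":
            cohort = require(stage, "cohort")
            score = build_prs(cohort)
            overall = wald_iv(cohort, score)
            subgroups = (subgroup_mr(cohort, score, "sex")
                         + subgroup_mr(cohort, score, "age_band")
                         + subgroup_mr(cohort, score, "menopause"))
            nl = nonlinear_mr(cohort, score)
            rows = [dataclasses.asdict(e) for e in [overall] + subgroups
                    + nl.strata]
            fo = out / "mr_onesample.tsv"
            pd.DataFrame(rows).to_csv(fo, sep="\t", index=False)
            fn = out / "mr_nonlinear.json"
            fn.write_text(json.dumps({
                "Q": nl.Q, "Q_df": nl.Q_df, "Q_p": nl.Q_p,
                "metareg_slope": nl.metareg_slope,
                "metareg_slope_se": nl.metareg_slope_se,
                "nonlin_p": nl.nonlin_p,
            }))
            state["mr1s"] = ([overall] + subgroups, nl)
            record(stage, [fo, fn])
        elif stage == "pleio":
            ss1, ss2 = require(stage, "ss1"), require(stage, "ss2")
            panel = require(stage, "panel")
            fit = require(stage, "ldsc_fit")
            nc = estimate_null_corr(ss1, ss2, fit)
            draws = null_stat_draws(nc, config.n_mc_draws, seed)
            hits = pleio_scan(ss1, ss2, panel, nc, mc_draws=draws,
                              p1=config.pleio_p1, p2=config.pleio_p2)
            df = pd.DataFrame([dataclasses.asdict(h) for h in hits])
            fp = out / "pleio_hits.tsv"
            df.to_csv(fp, sep="\t", index=False)
            state["hits"] = hits
            record(stage, [fp])
        elif stage == "finemap":
            ss1 = require(stage, "ss1")
            hits = require(stage, "hits")
            sets = []
            for h in hits:
                if not h.significant:
                    continue
                locus = ss1.df[(ss1.df["CHR"] == h.chr)
                               & (ss1.df["POS"] >= h.window_start)
                               & (ss1.df["POS"] <= h.window_end)]
                cs = credible_set(locus, locus_id=h.snp)
                sets.append({"locus": h.snp, "size": cs.size,
                             "top": cs.table["snp"].iloc[0],
                             "top_posterior": float(cs.table["posterior"].iloc[0])})
            ff = out / "credible_sets.tsv"
            pd.DataFrame(sets).to_csv(ff, sep="\t", index=False)
            state["credible_sets"] = sets
            record(stage, [ff])
        elif stage == "coloc":
            ss1, ss2 = require(stage, "ss1"), require(stage, "ss2")
            hits = require(stage, "hits")
            rows = []
            for h in hits:
                if not h.significant:
                    continue
                lx = ss1.df[(ss1.df["CHR"] == h.chr)
                            & (ss1.df["POS"] >= h.window_start)
                            & (ss1.df["POS"] <= h.window_end)]
                ly = ss2.df[(ss2.df["CHR"] == h.chr)
                            & (ss2.df["POS"] >= h.window_start)
                            & (ss2.df["POS"] <= h.window_end)]
                res = coloc(lx, ly, locus_id=h.snp)
                rows.append({"locus": h.snp, **res.as_dict(),
                             "colocalized": res.colocalized})
            fc = out / "coloc.tsv"
            pd.DataFrame(rows).to_csv(fc, sep="\t", index=False)
            state["coloc"] = rows
            record(stage, [fc])
        elif stage == "report":
            published = load_published_hits()
            sig = apply_significance_filter(published)
            col = apply_coloc_rule(published)
            summary = {
                "published_loci": int(len(published)),
                "published_significant": int(len(sig)),
                "published_colocalized": int(col["colocalized"].sum()),
            }
            if "ldsc_fit" in state:
                f = state["ldsc_fit"]
                summary.update(h2_exposure=f.h2, h2_outcome=f.h2_2,
                               rg=f.rg, rg_p=f.rg_p)
            if "local" in state:
                summary["local_significant_regions"] = int(
                    sum(r.significant for r in state["local"]))
            fr = out / "report.json"
            fr.write_text(json.dumps(summary))
            state["report"] = summary
            record(stage, [fr])

    fm = out / "manifest.json"
    fm.write_text(json.dumps(manifest, indent=2))
    return manifest
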