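#!/usr/bin/env python
"""Two-sample Mendelian randomization battery.

Selects instruments from the exposure GWAS (10-Mb clumping, r2 < 0.01,
p < 5e-8), harmonizes against the outcome GWAS, and runs IVW, MR-Egger,
the weighted median, MR-PRESSO, leave-one-out and Steiger filtering.
The simulated truth is a null causal effect, so every estimator should
bracket zero.  Writes results/mr_twosample.tsv.
"""

import dataclasses
import pathlib

import pandas as pd

import crosstrait as ct

SEED = 2024


def main() -> None:
    out = pathlib.Path("results")
    data = out / "data"
    panel = ct.LDPanel.read(data / "ld_panel_iv")
    ss1 = ct.read_sumstats(data / "sumstats_iv_exposure.tsv", trait="25OHD")
    ss2 = ct.read_sumstats(data / "sumstats_iv_outcome.tsv", trait="eBMD")

    idx = ct.select_instruments(ss1, panel)
    hz = ct.harmonize(ss1, ss2)
    iv = hz.subset(hz.df["snp"].isin(idx["index_snp"]).to_numpy())
    print(f"{len(idx)} index SNVs selected; {iv.n_iv} harmonized instruments")

    fits = [ct.ivw(iv), ct.egger(iv),
            ct.weighted_median(iv, seed=SEED),
            ct.mr_presso(iv, seed=SEED)]
    filtered, removed = ct.steiger_filter(iv)
    f = ct.ivw(filtered)
    f.method = "ivw_steiger_filtered"
    fits.append(f)
    print(f"Steiger filter removed {len(removed)} SNV(s); "
          "simulated truth is a null causal effect")
    for fit in fits:
        print(f"  {fit.method:22s} beta {fit.beta:+.4f} "
              f"(95% CI {fit.ci_low:+.4f} to {fit.ci_high:+.4f}, "
              f"p = {fit.p:.2f})")
    pd.DataFrame([dataclasses.asdict(f) for f in fits]).to_csv(
        out / "mr_twosample.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
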