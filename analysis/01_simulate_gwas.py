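#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds the LD reference panel, a pair of overlapping-sample GWAS summary
statistic sets at the study's heritabilities (0.10 for the vitamin-D
exposure, 0.27 for heel bone density) with a null genetic correlation, and
an individual-level cohort carrying 143 instrument SNVs.  Writes everything
under results/data/ for the downstream stages.
"""

import numpy as np

import crosstrait as ct

OUT = "results/data"
SEED = 2024


def main() -> None:
    arch = ct.ArchitectureConfig(
        n_blocks=100, block_size=50, n1=20_000, n2=20_000,
        n_overlap=10_000, rho_e=0.1, rg=0.0, prop_shared=0.0,
        prop_causal_1=1.0, prop_causal_2=1.0, seed=SEED)
    panel = ct.make_ld_panel(arch)
    ss1, ss2, truth = ct.simulate_sumstats(arch, panel)
    cohort = ct.simulate_cohort(ct.CohortConfig(
        n=20_000, subgroup_effects={"sex": {"male": 0.1, "female": 0.0}},
        seed=SEED + 1))

    # a second pair with 143 planted detectable exposure hits and no causal
    # exposure->outcome link, for instrument selection and two-sample MR
    arch_iv = ct.ArchitectureConfig(
        n_blocks=200, block_size=25, n1=100_000, n2=100_000, n_overlap=0,
        h2_1=0.3, h2_2=0.27, prop_causal_1=143 / 5000, prop_causal_2=0.1,
        prop_shared=0.0, effect_dist="fixed", causal_placement="spread",
        seed=SEED + 2)
    panel_iv = ct.make_ld_panel(arch_iv)
    iv1, iv2, truth_iv = ct.simulate_sumstats(arch_iv, panel_iv)

    import pathlib
    out = pathlib.Path(OUT)
    out.mkdir(parents=True, exist_ok=True)
    panel.write(out / "ld_panel")
    ct.write_sumstats(ss1, out / "sumstats_exposure.tsv")
    ct.write_sumstats(ss2, out / "sumstats_outcome.tsv")
    truth.to_json(out / "truth.json")
    panel_iv.write(out / "ld_panel_iv")
    ct.write_sumstats(iv1, out / "sumstats_iv_exposure.tsv")
    ct.write_sumstats(iv2, out / "sumstats_iv_outcome.tsv")
    truth_iv.to_json(out / "truth_iv.json")
    cohort.write(out / "cohort.tsv")

    print(f"panel: {panel.n_blocks} blocks x {arch.block_size} SNVs")
    print(f"exposure GWAS: {len(ss1)} SNVs, mean chi2 "
          f"{np.mean(ss1.z**2):.3f}")
    print(f"outcome GWAS:  {len(ss2)} SNVs, mean chi2 "
          f"{np.mean(ss2.z**2):.3f}")
    print(f"instrument-discovery GWAS: {len(truth_iv.causal_1)} planted "
          f"exposure hits, null causal link to the outcome")
    print(f"cohort: {cohort.n} persons, {len(cohort.snv_ids)} instrument "
          f"SNVs (male-specific causal effect 0.1 planted)")


if __name__ == "__main__":
    main()
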