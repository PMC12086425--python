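#!/usr/bin/env python
"""Fine-mapping and colocalization at simulated loci.

Per locus with one causal variant: the 99% credible set from the flat-prior
Wakefield ABFs, then two-trait colocalization — shared-variant loci should
reach PPH4 > 0.75 and distinct-variant loci should favour PPH3.
Writes results/finemap_coloc.tsv.
"""

import pathlib

import numpy as np
import pandas as pd

import crosstrait as ct

SEED = 2024


def main() -> None:
    rng = np.random.default_rng(SEED + 41)
    m, n = 50, 50_000
    cfg = ct.ArchitectureConfig(n_blocks=1, block_size=m, ld_decay=0.8,
                                seed=0)
    panel = ct.make_ld_panel(cfg)
    R = panel.blocks[0]
    L = np.linalg.cholesky(R + 1e-12 * np.eye(m))
    se = 1.0 / np.sqrt(n)

    def locus(causal):
        beta = np.zeros(m)
        beta[causal] = 7.0 / np.sqrt(n)
        z = np.sqrt(n) * R @ beta + L @ rng.standard_normal(m)
        return pd.DataFrame({"SNP": [f"v{i}" for i in range(m)],
                             "POS": np.arange(m) + 1,
                             "BETA": z * se, "SE": se})

    rows = []
    covered = 0
    n_loci = 100
    for i in range(n_loci):
        causal = int(rng.integers(0, m))
        lx = locus(causal)
        cs = ct.credible_set(lx, coverage=0.99, locus_id=f"locus{i}")
        covered += f"v{causal}" in cs.snvs
        shared = ct.coloc(lx, locus(causal), locus_id=f"locus{i}")
        distinct = ct.coloc(lx, locus((causal + 25) % m))
        rows.append({"locus": f"locus{i}", "credible_size": cs.size,
                     "covered": f"v{causal}" in cs.snvs,
                     "pph4_shared": shared.pph4,
                     "pph3_distinct": distinct.pph3})
    df = pd.DataFrame(rows)
    df.to_csv(pathlib.Path("results") / "finemap_coloc.tsv", sep="\t",
              index=False)
    print(f"99% credible sets cover the causal variant in "
          f"{covered}/{n_loci} loci (median size "
          f"{df['credible_size'].median():.0f})")
    print(f"shared-variant loci with PPH4 > 0.75: "
          f"{(df['pph4_shared'] > 0.75).mean():.0%}")
    print(f"distinct-variant loci median PPH3: "
          f"{df['pph3_distinct'].median():.3f}")


if __name__ == "__main__":
    main()
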