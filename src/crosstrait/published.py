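"""The published cross-trait index-SNV table for 25OHD and heel BMD.

Bundles the 49 pleiotropic index SNVs reported for the serum
25-hydroxyvitamin D / estimated heel bone-mineral-density pair — per-trait
effects and p-values, the pleiotropy p-value and the colocalization PPH4 as
printed — so the significance and colocalization rules can be exercised on
real published numbers without any external lookup.  PPH4 values printed
below the table's resolution ("<0.001") are parsed as that upper bound;
they sit far below the 0.75 colocalization rule either way.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .coloc import classify_colocalized
from .pleio import P_PLEIO_THRESH, P_SINGLE_THRESH

__all__ = ["load_published_hits", "apply_significance_filter",
           "apply_coloc_rule"]


def _parse_bounded(v: str) -> float:
    v = str(v).strip()
    if v.startswith("<"):
        return float(v[1:])
    return float(v)


def load_published_hits() -> pd.DataFrame:
    """Published 49-locus table as a DataFrame (one row per index SNV)."""
    with resources.files("crosstrait.data").joinpath(
            "published_hits.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"pph4": str})
    df["pph4"] = df["pph4"].map(_parse_bounded)
    df["reported_novel"] = df["reported_novel"].astype(bool)
    df["single_variant_credible_set"] = (
        df["single_variant_credible_set"].astype(bool))
    return df


def apply_significance_filter(
    hits: pd.DataFrame,
    p_pleio: float = P_PLEIO_THRESH,
    p_single: float = P_SINGLE_THRESH,
) -> pd.DataFrame:
    """Retain loci with P_pleio < 5e-8 and both single-trait P < 1e-5."""
    keep = ((hits["p_pleio"] < p_pleio)
            & (hits["p_exposure"] < p_single)
            & (hits["p_outcome"] < p_single))
    return hits.loc[keep].reset_index(drop=True)


def apply_coloc_rule(hits: pd.DataFrame, threshold: float = 0.75) -> pd.DataFrame:
    """Flag colocalized loci (PPH4 > threshold, strict) in the table."""
    return classify_colocalized(hits, threshold=threshold)
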