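"""Candidate selection: the four-criterion union over the enrichment
and carrier-frequency metrics, plus the gene-list alternate filter."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .filtering import HIGH_IMPACT

__all__ = ["SelectionCriteria", "select_candidates", "gene_list_filter"]


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds for the four selection routes (all inclusive):

    1. segregates in >= fam_min_many families, irrespective of carrier
       frequency;
    2. frequency ratio >= ratio_high with max average carrier frequency
       >= ratio_high_max_avg_min (percent);
    3. min average carrier frequency >= min_avg_min — the true average
       carrier frequency can only be higher;
    4. max average carrier frequency >= max_avg_min.
    """

    fam_min_many: int = 6
    ratio_high: float = 4.0
    ratio_high_max_avg_min: float = 40.0
    min_avg_min: float = 50.0
    max_avg_min: float = 67.0


def select_candidates(metrics: pd.DataFrame,
                      criteria: SelectionCriteria = SelectionCriteria(),
                      ) -> pd.DataFrame:
    """Apply the four-criterion union.

    ``metrics`` needs columns: variant_id, n_segregating_families,
    frequency_ratio, min_avg, max_avg (percent).  Rows with any metric
    missing are excluded with a warning.  Returns the frame with
    boolean columns crit_many_families, crit_ratio_carrier,
    crit_min_avg, crit_max_avg, selected, and n_criteria.
    """
    needed = ["variant_id", "n_segregating_families", "frequency_ratio",
              "min_avg", "max_avg"]
    missing_cols = [c for c in needed if c not in metrics.columns]
    if missing_cols:
        raise ValueError(f"metrics table lacks columns {missing_cols}")
    df = metrics.copy()
    bad = df[needed].isna().any(axis=1)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} variants excluded from selection for missing "
            "metrics", stacklevel=2)
        df = df[~bad].copy()
    c = criteria
    df["crit_many_families"] = df["n_segregating_families"] >= c.fam_min_many
    df["crit_ratio_carrier"] = ((df["frequency_ratio"] >= c.ratio_high)
                                & (df["max_avg"] >= c.ratio_high_max_avg_min))
    df["crit_min_avg"] = df["min_avg"] >= c.min_avg_min
    df["crit_max_avg"] = df["max_avg"] >= c.max_avg_min
    flags = df[["crit_many_families", "crit_ratio_carrier",
                "crit_min_avg", "crit_max_avg"]]
    df["n_criteria"] = flags.sum(axis=1)
    df["selected"] = df["n_criteria"] >= 1
    return df


def gene_list_filter(variants, panel, gene_list, af_threshold: float = 0.02):
    """Alternate filter: high-impact variants in listed genes with
    population frequency strictly below the threshold in every
    reference population, regardless of family count."""
    genes = set(gene_list)
    if not genes:
        return []
    out = []
    for v in variants:
        if v.consequence not in HIGH_IMPACT or v.gene not in genes:
            continue
        freqs = panel.variant_freqs(v.vid)
        if all(af < af_threshold for af in freqs.values()):
            out.append(v)
    return out
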