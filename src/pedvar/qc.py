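"""Post-genotyping quality control for the follow-up genotype matrix.

Sample filter: call rate >= 70% (strict removal below).  Variant
filters, applied in order with each removal attributed to the first
failing rule: call rate < 70%, carrier frequency > 2% in study
controls, present in fewer than the minimum number of families.
Membership in the removed set is order-independent; only attribution
depends on rule order.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["sample_qc", "variant_qc", "concordance"]


def _call_rate(frame: pd.DataFrame, axis: int) -> pd.Series:
    return frame.notna().mean(axis=axis)


def sample_qc(matrix: pd.DataFrame, call_rate_min: float = 0.70):
    """Drop samples (rows) with call rate strictly below the threshold.

    Returns (filtered matrix, report frame of removed samples).
    """
    if matrix.empty:
        raise ValueError("genotype matrix is empty")
    rates = _call_rate(matrix, axis=1)
    keep = rates >= call_rate_min
    report = pd.DataFrame({"sample": rates.index[~keep],
                           "call_rate": rates[~keep].values})
    return matrix.loc[keep], report


def variant_qc(matrix: pd.DataFrame, sample_info: pd.DataFrame,
               call_rate_min: float = 0.70, control_freq_max: float = 0.02,
               fam_min: int = 3):
    """Drop variants (columns) failing any of the three rules.

    ``sample_info`` is indexed like the matrix rows with columns
    ``is_control`` (bool) and ``family_id`` (label or NA for
    case-control subjects).  Control frequency is the carrier frequency
    among called controls (strict >); family presence counts families
    with at least one carrier among called family members.

    Returns (filtered matrix, report frame with one row per removed
    variant and its attributed rule).
    """
    info = sample_info.loc[matrix.index]
    controls = matrix.loc[info["is_control"].fillna(False).astype(bool)]
    fam = info["family_id"]
    removed = []
    keep = []
    for v in matrix.columns:
        col = matrix[v]
        rate = col.notna().mean()
        if rate < call_rate_min:
            removed.append({"variant": v, "rule": "call_rate", "value": rate})
            continue
        ctrl = controls[v].dropna()
        cfreq = float((ctrl > 0).mean()) if len(ctrl) else 0.0
        if cfreq > control_freq_max:
            removed.append({"variant": v, "rule": "control_freq", "value": cfreq})
            continue
        carriers = col.dropna() > 0
        nfam = fam[col.index][carriers.reindex(col.index, fill_value=False)].dropna().nunique()
        if nfam < fam_min:
            removed.append({"variant": v, "rule": "family_count", "value": nfam})
            continue
        keep.append(v)
    report = pd.DataFrame(removed, columns=["variant", "rule", "value"])
    return matrix[keep], report


def concordance(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> float:
    """Fraction of matching calls among jointly non-missing entries of
    two genotype matrices aligned on shared samples and variants."""
    common_rows = calls_a.index.intersection(calls_b.index)
    common_cols = calls_a.columns.intersection(calls_b.columns)
    a = calls_a.loc[common_rows, common_cols]
    b = calls_b.loc[common_rows, common_cols]
    joint = a.notna() & b.notna()
    n = int(joint.values.sum())
    if n == 0:
        raise ValueError("no jointly non-missing calls to compare")
    match = int(((a == b) & joint).values.sum())
    return match / n
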