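"""Published summary statistics bundled as analysis inputs.

Per-study association results for the nine prostate-cancer risk
variants identified in the 75-family discovery set, as reported for
the FHCRC population-based case-control study (1,265 cases / 1,230
controls) and the PLCO nested case-control study (4,222 cases / 2,899
controls), along with the stratified contingency tables and the
risk-score category counts.  These are the inputs from which the
pooled (meta-analysis) quantities are recomputed; nothing here is a
pipeline output.

Odds ratios are age-adjusted dominant-model estimates; frequencies are
carrier frequencies in percent.
"""

from __future__ import annotations

from .assoc import AssocResult

STUDY_SIZES = {"FHCRC": (1265, 1230), "PLCO": (4222, 2899)}

# variant -> study -> (OR, ci_low, ci_high, case_freq_pct, control_freq_pct)
NINE_VARIANT_STUDY_RESULTS = {
    "EPHA8_p.Pro607His":   {"FHCRC": (2.70, 1.20, 6.07, 2.50, 0.94),
                            "PLCO": (0.97, 0.69, 1.39, 1.82, 1.86)},
    "D2HGDH_p.Ala225Thr":  {"FHCRC": (2.37, 1.23, 4.56, 2.46, 1.06),
                            "PLCO": (0.80, 0.55, 1.16, 1.46, 1.87)},
    "OR5H14_p.Met59Val":   {"FHCRC": (1.85, 1.02, 3.36, 2.54, 1.39),
                            "PLCO": (1.27, 0.92, 1.78, 2.42, 1.93)},
    "BRD2_p.Ala605Pro":    {"FHCRC": (4.99, 1.09, 22.86, 0.79, 0.16),
                            "PLCO": (0.87, 0.49, 1.57, 0.62, 0.73)},
    "HOXB13_p.Gly84Glu":   {"FHCRC": (5.68, 1.67, 19.36, 1.42, 0.25),
                            "PLCO": (3.78, 1.94, 8.28, 1.11, 0.31)},
    "CHAD_p.Ala342Asp":    {"FHCRC": (3.51, 1.30, 9.49, 1.43, 0.41),
                            "PLCO": (1.28, 0.81, 2.06, 1.23, 0.97)},
    "SWSAP1_p.Leu118Ile":  {"FHCRC": (2.61, 1.34, 5.09, 2.55, 0.98),
                            "PLCO": (1.12, 0.75, 1.70, 1.44, 1.31)},
    "TANGO2_p.Ser17Ter":   {"FHCRC": (1.93, 1.08, 3.42, 2.77, 1.47),
                            "PLCO": (1.39, 0.98, 1.99, 2.30, 1.66)},
    "PPP6R2_p.Arg103His":  {"FHCRC": (2.02, 1.03, 3.96, 2.07, 1.06),
                            "PLCO": (1.09, 0.76, 1.58, 1.83, 1.66)},
}

# First-degree-family-history strata, pooled over both studies:
# variant -> stratum -> (case_noncarrier, case_carrier,
#                        control_noncarrier, control_carrier)
FAMILY_HISTORY_TABLES = {
    "HOXB13_p.Gly84Glu": {"no": (4596, 49, 3697, 11),
                          "yes": (733, 13, 340, 1)},
    "TANGO2_p.Ser17Ter": {"no": (4531, 114, 3655, 56),
                          "yes": (728, 17, 333, 8)},
    "OR5H14_p.Met59Val": {"no": (4526, 113, 3645, 65),
                          "yes": (724, 20, 335, 6)},
    "CHAD_p.Ala342Asp":  {"no": (4582, 59, 3675, 31),
                          "yes": (737, 9, 339, 2)},
}

# Aggressiveness strata (pooled): variant -> stratum -> (noncarrier, carrier)
AGGRESSIVENESS_TABLES = {
    "HOXB13_p.Gly84Glu": {"control": (4110, 12), "non-aggressive": (4347, 47),
                          "aggressive": (1074, 18)},
    "TANGO2_p.Ser17Ter": {"control": (4059, 66), "non-aggressive": (4298, 97),
                          "aggressive": (1055, 35)},
    "OR5H14_p.Met59Val": {"control": (4051, 73), "non-aggressive": (4278, 111),
                          "aggressive": (1066, 23)},
    "CHAD_p.Ala342Asp":  {"control": (4087, 33), "non-aggressive": (4336, 56),
                          "aggressive": (1076, 14)},
}

# Risk-allele count categories over the four pooled-analysis risk
# variants (complete cases across all four): category -> (cases, controls)
RISK_SCORE_COUNTS = {"0": (5087, 3928), "1": (367, 178), "2-3": (17, 3)}

# Co-occurrence inputs: pooled case count and pooled case carrier
# frequencies (fractions) of the two co-occurring variants.
COOCCURRENCE_INPUTS = {"n_cases": 5487, "f_hoxb13": 0.0118, "f_tango2": 0.0241}


def study_results(variant: str) -> list[AssocResult]:
    """The two per-study results for a variant as AssocResult objects,
    ready for meta-analysis."""
    out = []
    for study, (or_, lo, hi, _cf, _kf) in NINE_VARIANT_STUDY_RESULTS[variant].items():
        out.append(AssocResult(variant=variant, study=study, or_=or_,
                               ci_low=lo, ci_high=hi, method="published"))
    return out


def combined_case_carrier_freq(variant: str) -> float:
    """Pooled case carrier frequency (percent) from the per-study
    frequencies weighted by study case counts."""
    total = carriers = 0.0
    for study, (_o, _l, _h, case_freq, _kf) in \
            NINE_VARIANT_STUDY_RESULTS[variant].items():
        n = STUDY_SIZES[study][0]
        carriers += case_freq / 100.0 * n
        total += n
    return 100.0 * carriers / total
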