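"""Case-control validation statistics.

All association tests assume a dominant genetic model: carriers of at
least one alternate allele versus homozygotes for the most common
allele.  The module provides the age-adjusted unconditional logistic
regression, the closed-form crude odds ratio used as its oracle,
Fisher's exact test in three conventions, polytomous (multinomial)
regression for disease-aggressiveness strata, fixed-effect
inverse-variance meta-analysis of study odds ratios, the risk-allele
count score, and the two-variant co-occurrence analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "AssocResult",
    "SeparationError",
    "crude_or",
    "logistic_dominant",
    "fisher_exact",
    "polytomous_logistic",
    "meta_fixed",
    "genetic_risk_score",
    "risk_score_table",
    "cooccurrence_expected",
    "cooccurrence_test",
    "stratified_analysis",
]

Z95 = 1.959964  # two-sided 95% normal quantile


class SeparationError(ValueError):
    """Raised when a logistic fit (or a meta-analysis input) has an
    empty carrier cell; callers should fall back to fisher_exact."""


@dataclass
class AssocResult:
    """An odds ratio with its Wald 95% CI and p-value."""

    variant: str
    stratum: str = "overall"
    study: str = "all"
    or_: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    n_case_carriers: int | None = None
    n_case_noncarriers: int | None = None
    n_control_carriers: int | None = None
    n_control_noncarriers: int | None = None
    method: str = ""

    @property
    def log_or(self) -> float:
        return math.log(self.or_)

    @property
    def se_log_or(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2 * Z95)

    def summary(self) -> str:
        return (f"{self.variant} [{self.study}/{self.stratum}] "
                f"OR={self.or_:.2f} (95% CI {self.ci_low:.2f}-{self.ci_high:.2f}) "
                f"P={self.p:.3g} ({self.method})")


# ----------------------------------------------------------- 2x2 tools

def crude_or(a: int, b: int, c: int, d: int, variant: str = "",
             stratum: str = "overall", study: str = "all") -> AssocResult:
    """Closed-form odds ratio from a 2x2 table
    (case carriers a, case non-carriers b, control carriers c, control
    non-carriers d): OR = ad/bc with the Wald CI
    exp(ln OR +/- 1.96 sqrt(1/a + 1/b + 1/c + 1/d))."""
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a == 0 and c == 0) or (b == 0 and d == 0):
        raise SeparationError("a carrier margin is empty; no association computable")
    if 0 in (a, b, c, d):
        raise SeparationError(
            "zero cell in the 2x2 table; the Wald CI is undefined — use "
            "fisher_exact")
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = abs(math.log(or_)) / se
    return AssocResult(
        variant=variant, stratum=stratum, study=study, or_=or_,
        ci_low=math.exp(math.log(or_) - Z95 * se),
        ci_high=math.exp(math.log(or_) + Z95 * se),
        p=2 * stats.norm.sf(z),
        n_case_carriers=a, n_case_noncarriers=b,
        n_control_carriers=c, n_control_noncarriers=d, method="crude")


def fisher_exact(a: int, b: int, c: int, d: int,
                 mode: str = "two_sided") -> float:
    """Fisher's exact p-value for the 2x2 table (a, b / c, d).

    Modes: ``two_sided`` (minimum-likelihood convention: sum of tables
    whose point probability does not exceed the observed table's),
    ``one_sided`` (enrichment of a), and ``point`` (hypergeometric
    probability of the observed table exactly).  Degenerate margins
    give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + c == 0) or (b + d == 0) or (a + b == 0) or (c + d == 0):
        return 1.0
    if mode == "two_sided":
        return float(stats.fisher_exact([[a, b], [c, d]])[1])
    if mode == "one_sided":
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="greater")[1])
    if mode == "point":
        n_total = a + b + c + d
        return float(stats.hypergeom.pmf(a, n_total, a + c, a + b))
    raise ValueError(f"unknown mode {mode!r}")


# --------------------------------------------------------- regressions

def _dominant_frame(cohort: pd.DataFrame, variant: str,
                    covariates: tuple[str, ...]) -> pd.DataFrame:
    cols = ["status", variant, *covariates]
    df = cohort[cols].dropna()
    return df


def _table_counts(df: pd.DataFrame, variant: str) -> tuple[int, int, int, int]:
    case = df["status"] == "case"
    carrier = df[variant] > 0
    return (int((case & carrier).sum()), int((case & ~carrier).sum()),
            int((~case & carrier).sum()), int((~case & ~carrier).sum()))


def logistic_dominant(cohort: pd.DataFrame, variant: str,
                      covariates: tuple[str, ...] = ("age",),
                      study: str = "all", stratum: str = "overall",
                      ) -> AssocResult:
    """Unconditional logistic regression of case status on dominant
    carrier coding, adjusted for the given covariates (age by default,
    continuous).  Subjects with a missing genotype are dropped
    listwise.  Separation (an empty carrier cell) raises
    SeparationError directing the caller to fisher_exact."""
    df = _dominant_frame(cohort, variant, covariates)
    a, b, c, d = _table_counts(df, variant)
    if a == 0 and c == 0:
        raise SeparationError(f"{variant}: no carriers in the analysis set")
    if a == 0 or c == 0:
        raise SeparationError(
            f"{variant}: zero {'case' if a == 0 else 'control'} carriers — "
            "logistic fit would separate; use fisher_exact")
    y = (df["status"] == "case").astype(float)
    X = sm.add_constant(
        df[[variant, *covariates]].astype(float), has_constant="add")
    res = sm.Logit(y, X).fit(disp=0)
    coef = res.params[variant]
    lo, hi = res.conf_int().loc[variant]
    return AssocResult(
        variant=variant, stratum=stratum, study=study,
        or_=math.exp(coef), ci_low=math.exp(lo), ci_high=math.exp(hi),
        p=float(res.pvalues[variant]),
        n_case_carriers=a, n_case_noncarriers=b,
        n_control_carriers=c, n_control_noncarriers=d,
        method="logistic" + ("" if not covariates else "+".join(("",) + covariates)))


_STRATA = ("non-aggressive", "aggressive")


def polytomous_logistic(cohort: pd.DataFrame, variant: str,
                        covariates: tuple[str, ...] = ("age",),
                        study: str = "all") -> list[AssocResult]:
    """Polytomous (multinomial) logistic regression with a three-level
    outcome — control (reference), non-aggressive, aggressive — giving
    a per-stratum OR/CI/p versus controls."""
    cols = ["aggressiveness", variant, *covariates]
    df = cohort[cols].dropna()
    levels = ["control", *_STRATA]
    for lev in levels:
        if not (df["aggressiveness"] == lev).any():
            raise ValueError(f"empty outcome stratum {lev!r}")
    y = pd.Categorical(df["aggressiveness"], categories=levels).codes
    X = sm.add_constant(
        df[[variant, *covariates]].astype(float), has_constant="add")
    for j, lev in enumerate(_STRATA):
        sub = df[(df["aggressiveness"] == "control")
                 | (df["aggressiveness"] == lev)]
        carr = sub[variant] > 0
        case = sub["aggressiveness"] == lev
        if not (carr & case).any() or not (carr & ~case).any():
            raise SeparationError(
                f"{variant}: empty carrier cell in stratum {lev!r}")
    res = sm.MNLogit(y, X).fit(disp=0, maxiter=200)
    out = []
    vix = list(X.columns).index(variant)
    for j, lev in enumerate(_STRATA):
        coef = float(res.params.iloc[vix, j])
        se = float(res.bse.iloc[vix, j])
        z = abs(coef) / se
        sub = df[df["aggressiveness"].isin(["control", lev])]
        carrier = sub[variant] > 0
        case = sub["aggressiveness"] == lev
        out.append(AssocResult(
            variant=variant, stratum=lev, study=study,
            or_=math.exp(coef), ci_low=math.exp(coef - Z95 * se),
            ci_high=math.exp(coef + Z95 * se), p=2 * stats.norm.sf(z),
            n_case_carriers=int((case & carrier).sum()),
            n_case_noncarriers=int((case & ~carrier).sum()),
            n_control_carriers=int((~case & carrier).sum()),
            n_control_noncarriers=int((~case & ~carrier).sum()),
            method="polytomous" + "".join(f"+{c}" for c in covariates)))
    return out


# ------------------------------------------------------- meta-analysis

def meta_fixed(inputs: list[AssocResult], variant: str | None = None,
               stratum: str = "overall") -> AssocResult:
    """Fixed-effect inverse-variance pooling of study log odds ratios.

    Standard errors come from each study's 95% CI as
    (ln U - ln L) / (2 x 1.959964).  A study with zero control
    carriers is refused (SeparationError): its CI is not interpretable
    and the comparison falls back to Fisher's exact test.
    """
    if not inputs:
        raise ValueError("meta_fixed requires at least one study result")
    for r in inputs:
        if r.n_control_carriers == 0:
            raise SeparationError(
                f"study {r.study} has no control carriers; meta-analysis "
                "not performed — use fisher_exact")
    logs = np.array([r.log_or for r in inputs])
    ses = np.array([r.se_log_or for r in inputs])
    w = 1.0 / ses**2
    pooled = float((w * logs).sum() / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    z = abs(pooled) / se
    return AssocResult(
        variant=variant or inputs[0].variant, stratum=stratum, study="meta",
        or_=math.exp(pooled), ci_low=math.exp(pooled - Z95 * se),
        ci_high=math.exp(pooled + Z95 * se), p=2 * stats.norm.sf(z),
        n_case_carriers=_sum_or_none(inputs, "n_case_carriers"),
        n_case_noncarriers=_sum_or_none(inputs, "n_case_noncarriers"),
        n_control_carriers=_sum_or_none(inputs, "n_control_carriers"),
        n_control_noncarriers=_sum_or_none(inputs, "n_control_noncarriers"),
        method="fixed-effect meta")


def _sum_or_none(inputs, attr):
    vals = [getattr(r, attr) for r in inputs]
    return None if any(v is None for v in vals) else int(sum(vals))


# ----------------------------------------------------------- risk score

RISK_CATEGORIES = ("0", "1", "2-3", ">=1")


def risk_score_table(case_counts: dict[str, int],
                     control_counts: dict[str, int]) -> pd.DataFrame:
    """Percentages and crude ORs (versus the zero-allele category) for
    risk-allele count categories.  Counts are keyed by category label
    from RISK_CATEGORIES; the '>=1' row is derived when absent."""
    cc, kc = dict(case_counts), dict(control_counts)
    if ">=1" not in cc:
        cc[">=1"] = cc.get("1", 0) + cc.get("2-3", 0)
        kc[">=1"] = kc.get("1", 0) + kc.get("2-3", 0)
    n_cases = cc["0"] + cc.get("1", 0) + cc.get("2-3", 0)
    n_controls = kc["0"] + kc.get("1", 0) + kc.get("2-3", 0)
    rows = []
    for cat in RISK_CATEGORIES:
        a, c = cc.get(cat, 0), kc.get(cat, 0)
        row = {"category": cat, "n_cases": a,
               "pct_cases": 100.0 * a / n_cases,
               "n_controls": c, "pct_controls": 100.0 * c / n_controls}
        if cat != "0" and min(a, c) > 0:
            r = crude_or(a, cc["0"], c, kc["0"], variant="risk_score",
                         stratum=cat)
            row.update(or_=r.or_, ci_low=r.ci_low, ci_high=r.ci_high, p=r.p)
        rows.append(row)
    return pd.DataFrame(rows)


def genetic_risk_score(cohort: pd.DataFrame, variants: list[str],
                       ) -> pd.DataFrame:
    """Risk-allele count score: dominant indicator per variant, summed.
    Only subjects with calls for every variant in the set are scored
    (complete-case)."""
    df = cohort.dropna(subset=list(variants))
    score = (df[list(variants)] > 0).sum(axis=1)

    def cat(s: int) -> str:
        return "0" if s == 0 else ("1" if s == 1 else "2-3")

    labels = score.map(cat)
    case = df["status"] == "case"
    case_counts = labels[case].value_counts().to_dict()
    control_counts = labels[~case].value_counts().to_dict()
    for d in (case_counts, control_counts):
        d.setdefault("0", 0)
    return risk_score_table(case_counts, control_counts)


# -------------------------------------------------------- co-occurrence

def cooccurrence_expected(n_cases: int, f1: float, f2: float) -> float:
    """Expected number of cases carrying both variants under carrier
    independence: n_cases x f1 x f2."""
    for f in (f1, f2):
        if not 0.0 <= f <= 1.0:
            raise ValueError("carrier frequencies must be in [0, 1]")
    return n_cases * f1 * f2


def cooccurrence_test(cohort: pd.DataFrame, v1: str, v2: str,
                      mode: str = "point") -> dict:
    """Compare both-carriers against neither-carriers between cases and
    controls, plus the observed-versus-expected count of double-carrier
    cases under independence."""
    df = cohort.dropna(subset=[v1, v2])
    both = (df[v1] > 0) & (df[v2] > 0)
    neither = (df[v1] == 0) & (df[v2] == 0)
    case = df["status"] == "case"
    a = int((case & both).sum())
    b = int((case & neither).sum())
    c = int((~case & both).sum())
    d = int((~case & neither).sum())
    n_cases = int(case.sum())
    f1 = float((df.loc[case, v1] > 0).mean())
    f2 = float((df.loc[case, v2] > 0).mean())
    return {
        "cases_both": a, "cases_neither": b,
        "controls_both": c, "controls_neither": d,
        "expected_cases_both": cooccurrence_expected(n_cases, f1, f2),
        "fisher_p": fisher_exact(a, b, c, d, mode=mode),
    }


# ------------------------------------------------------- stratification

def stratified_analysis(cohort: pd.DataFrame, variant: str,
                        stratifier: str,
                        covariates: tuple[str, ...] = ("age",),
                        fisher_mode: str = "point") -> pd.DataFrame:
    """Per-study and meta-analysis results within strata.

    ``stratifier`` is ``family_history`` (logistic within yes/no
    strata, controls stratified alongside cases) or ``aggressiveness``
    (polytomous regression per study, pooled per stratum).  When a
    study stratum has no control carriers, the meta-analysis is
    refused and Fisher's exact test on the pooled counts is reported
    instead.
    """
    studies = sorted(cohort["study"].unique())
    rows: list[AssocResult] = []
    fisher_rows: list[dict] = []
    if stratifier == "family_history":
        for level in ("yes", "no"):
            sub = cohort[cohort["family_history"] == level]
            if sub.empty:
                continue
            per_study, failed = [], False
            for s in studies:
                ss = sub[sub["study"] == s]
                try:
                    per_study.append(
                        logistic_dominant(ss, variant, covariates, study=s,
                                          stratum=f"family_history={level}"))
                except SeparationError:
                    failed = True
            rows.extend(per_study)
            if failed or not per_study:
                a, b, c, d = _table_counts(
                    sub.dropna(subset=[variant]), variant)
                fisher_rows.append({
                    "variant": variant, "stratum": f"family_history={level}",
                    "study": "meta", "method": f"fisher_{fisher_mode}",
                    "p": fisher_exact(a, b, c, d, mode=fisher_mode),
                    "n_case_carriers": a, "n_case_noncarriers": b,
                    "n_control_carriers": c, "n_control_noncarriers": d})
            else:
                try:
                    rows.append(meta_fixed(per_study,
                                           stratum=f"family_history={level}"))
                except SeparationError:
                    a, b, c, d = _table_counts(
                        sub.dropna(subset=[variant]), variant)
                    fisher_rows.append({
                        "variant": variant,
                        "stratum": f"family_history={level}",
                        "study": "meta", "method": f"fisher_{fisher_mode}",
                        "p": fisher_exact(a, b, c, d, mode=fisher_mode),
                        "n_case_carriers": a, "n_case_noncarriers": b,
                        "n_control_carriers": c, "n_control_noncarriers": d})
    elif stratifier == "aggressiveness":
        by_stratum: dict[str, list[AssocResult]] = {s: [] for s in _STRATA}
        for s in studies:
            ss = cohort[cohort["study"] == s]
            for r in polytomous_logistic(ss, variant, covariates, study=s):
                by_stratum[r.stratum].append(r)
                rows.append(r)
        for stratum, per_study in by_stratum.items():
            rows.append(meta_fixed(per_study, stratum=stratum))
    else:
        raise ValueError(f"unknown stratifier {stratifier!r}")
    frame = pd.DataFrame([vars(r) for r in rows])
    if fisher_rows:
        frame = pd.concat([frame, pd.DataFrame(fisher_rows)],
                          ignore_index=True)
    return frame
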