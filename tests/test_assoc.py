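import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pedvar.assoc import (SeparationError, cooccurrence_expected,
                          cooccurrence_test, crude_or, fisher_exact,
                          genetic_risk_score, logistic_dominant, meta_fixed,
                          polytomous_logistic, risk_score_table,
                          stratified_analysis, AssocResult)
from pedvar.simulate import PlantedVariant, SimulationSpec, generate_cohort


def fisher_enum(a, b, c, d, mode):
    """Exhaustive hypergeometric enumeration with exact rational
    arithmetic via math.comb."""
    r1, r2, k = a + b, c + d, a + c
    n = r1 + r2
    lo, hi = max(0, k - r2), min(r1, k)
    denom = math.comb(n, k)
    probs = {x: math.comb(r1, x) * math.comb(r2, k - x) / denom
             for x in range(lo, hi + 1)}
    pa = probs[a]
    if mode == "point":
        return pa
    if mode == "one_sided":
        return sum(p for x, p in probs.items() if x >= a)
    return sum(p for p in probs.values() if p <= pa * (1 + 1e-9))


def null_cohort(rng, n=2000, carrier_freq=0.05):
    carrier = (rng.random(n) < carrier_freq).astype(float)
    status = np.where(rng.random(n) < 0.5, "case", "control")
    return pd.DataFrame({"status": status, "age": rng.normal(65, 8, n),
                         "v": carrier})


class TestCrudeOR:
    def test_worked_table(self):
        r = crude_or(35, 1055, 66, 4059)
        assert r.or_ == pytest.approx(2.0403, abs=1e-4)
        assert r.ci_low == pytest.approx(1.347, abs=1e-3)
        assert r.ci_high == pytest.approx(3.091, abs=1e-3)

    def test_symmetric_table_is_null(self):
        assert crude_or(1, 1, 1, 1).or_ == 1.0

    def test_empty_carrier_margin_errors(self):
        with pytest.raises(SeparationError):
            crude_or(0, 10, 0, 20)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500), st.integers(1, 500),
           st.integers(1, 500))
    def test_transpose_inverts_or(self, a, b, c, d):
        r1 = crude_or(a, b, c, d)
        r2 = crude_or(c, d, a, b)
        assert r1.or_ * r2.or_ == pytest.approx(1.0)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((13, 733, 1, 340), 0.032),   # family-history-positive stratum
        ((9, 737, 2, 339), 0.183),
    ])
    def test_point_probability_matches_reported(self, table, expected):
        assert fisher_exact(*table, mode="point") == pytest.approx(
            expected, abs=5e-4)

    def test_degenerate_margin_is_one(self):
        assert fisher_exact(0, 10, 0, 20) == 1.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.integers(0, 40), st.integers(0, 40), st.integers(0, 40),
           st.integers(0, 40), st.sampled_from(["two_sided", "one_sided",
                                                "point"]))
    def test_matches_exhaustive_enumeration(self, a, b, c, d, mode):
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            assert fisher_exact(a, b, c, d, mode) == 1.0
        else:
            assert fisher_exact(a, b, c, d, mode) == pytest.approx(
                fisher_enum(a, b, c, d, mode), rel=1e-8, abs=1e-12)


class TestLogisticDominant:
    def test_no_covariates_matches_crude_or(self, rng):
        """Saturated logistic equals the closed-form OR to 1e-6 on
        random tables."""
        for _ in range(100):
            a, b, c, d = rng.integers(5, 200, size=4)
            df = pd.DataFrame({
                "status": ["case"] * (a + b) + ["control"] * (c + d),
                "v": [1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d})
            fit = logistic_dominant(df, "v", covariates=())
            ref = crude_or(int(a), int(b), int(c), int(d))
            assert fit.or_ == pytest.approx(ref.or_, abs=1e-6, rel=1e-6)
            assert fit.ci_low == pytest.approx(ref.ci_low, rel=1e-4)

    def test_independent_age_barely_shifts_or(self):
        spec = SimulationSpec(seed=21, cohorts={"S": (3500, 3500)})
        pv = PlantedVariant(id="v", control_carrier_freq=0.05, cohort_or=2.0)
        df = generate_cohort(spec, [pv])
        adj = logistic_dominant(df, "v")
        crude = logistic_dominant(df, "v", covariates=())
        assert abs(math.log(adj.or_) - math.log(crude.or_)) < 0.02

    def test_zero_control_carriers_raise(self):
        df = pd.DataFrame({"status": ["case"] * 50 + ["control"] * 50,
                           "v": [1.0] * 5 + [0.0] * 95,
                           "age": 65.0})
        with pytest.raises(SeparationError, match="fisher"):
            logistic_dominant(df, "v")

    def test_planted_or_within_own_ci(self):
        hits = 0
        for seed in range(30):
            spec = SimulationSpec(seed=seed, cohorts={"S": (1300, 1300)})
            pv = PlantedVariant(id="v", control_carrier_freq=0.03,
                                cohort_or=4.0)
            df = generate_cohort(spec, [pv])
            r = logistic_dominant(df, "v")
            hits += r.ci_low <= 4.0 <= r.ci_high
        assert hits >= 26  # ~95% coverage


class TestPolytomous:
    def _cohort(self, seed=13, or_=2.0):
        spec = SimulationSpec(seed=seed, cohorts={"S": (2000, 2000)})
        pv = PlantedVariant(id="v", control_carrier_freq=0.05, cohort_or=or_)
        return generate_cohort(spec, [pv])

    def test_no_covariates_matches_stratum_crude_ors(self):
        df = self._cohort()
        results = polytomous_logistic(df, "v", covariates=())
        for r in results:
            ref = crude_or(r.n_case_carriers, r.n_case_noncarriers,
                           r.n_control_carriers, r.n_control_noncarriers)
            assert r.or_ == pytest.approx(ref.or_, rel=1e-4)

    def test_reported_aggressive_table_crude_or(self):
        # crude OR from the pooled aggressive-stratum counts
        r = crude_or(35, 1055, 66, 4059)
        assert r.or_ == pytest.approx(2.04, abs=0.005)

    def test_empty_stratum_rejected(self):
        df = self._cohort()
        df = df[df["aggressiveness"] != "aggressive"]
        with pytest.raises(ValueError, match="stratum"):
            polytomous_logistic(df, "v")


class TestMetaFixed:
    def test_single_study_identity(self):
        r = AssocResult(variant="v", study="A", or_=2.0, ci_low=1.5,
                        ci_high=8 / 3, n_control_carriers=5)
        pooled = meta_fixed([r])
        assert pooled.or_ == pytest.approx(2.0)
        assert pooled.ci_low == pytest.approx(1.5, rel=1e-6)

    def test_identical_studies_shrink_ci_by_sqrt2(self):
        r = AssocResult(variant="v", study="A", or_=2.0, ci_low=1.5,
                        ci_high=8 / 3, n_control_carriers=5)
        pooled = meta_fixed([r, r])
        assert pooled.or_ == pytest.approx(2.0)
        se_single = r.se_log_or
        se_pooled = pooled.se_log_or
        assert se_pooled == pytest.approx(se_single / math.sqrt(2), rel=1e-6)

    def test_matches_statsmodels_combine_effects(self, rng):
        from statsmodels.stats.meta_analysis import combine_effects

        for _ in range(20):
            k = int(rng.integers(2, 6))
            ors = rng.uniform(0.5, 5.0, size=k)
            ses = rng.uniform(0.1, 0.6, size=k)
            inputs = [AssocResult(variant="v", study=f"S{i}", or_=o,
                                  ci_low=math.exp(math.log(o) - 1.959964 * s),
                                  ci_high=math.exp(math.log(o) + 1.959964 * s),
                                  n_control_carriers=5)
                      for i, (o, s) in enumerate(zip(ors, ses))]
            pooled = meta_fixed(inputs)
            res = combine_effects(np.log(ors), ses**2)
            assert pooled.log_or == pytest.approx(
                float(res.mean_effect_fe), rel=1e-10)

    def test_zero_control_carrier_study_refused(self):
        bad = AssocResult(variant="v", study="A", or_=5.0, ci_low=1.0,
                          ci_high=25.0, n_control_carriers=0)
        with pytest.raises(SeparationError, match="fisher"):
            meta_fixed([bad])


class TestRiskScore:
    def test_percentages_sum_to_100(self):
        df = risk_score_table({"0": 500, "1": 40, "2-3": 10},
                              {"0": 600, "1": 20, "2-3": 2})
        base = df[df.category.isin(["0", "1", "2-3"])]
        assert base["pct_cases"].sum() == pytest.approx(100.0)
        assert base["pct_controls"].sum() == pytest.approx(100.0)

    def test_complete_case_scoring(self):
        df = pd.DataFrame({
            "status": ["case"] * 4 + ["control"] * 4,
            "v1": [1, 1, 0, np.nan, 0, 0, 1, 0],
            "v2": [1, 0, 0, 1, 0, 0, 1, 0],
        })
        tab = genetic_risk_score(df, ["v1", "v2"]).set_index("category")
        # the case with a missing v1 call is excluded entirely
        assert tab.loc["0", "n_cases"] == 1
        assert tab.loc["1", "n_cases"] == 1
        assert tab.loc["2-3", "n_cases"] == 1
        assert tab.loc[">=1", "n_controls"] == 1

    def test_all_zero_carriers(self):
        df = pd.DataFrame({"status": ["case", "control"],
                           "v1": [0.0, 0.0]})
        tab = genetic_risk_score(df, ["v1"]).set_index("category")
        assert tab.loc["0", "pct_cases"] == 100.0


class TestCooccurrence:
    def test_expected_is_product(self):
        assert cooccurrence_expected(1000, 0.02, 0.05) == 1.0
        assert cooccurrence_expected(500, 0.0, 0.3) == 0.0
        assert cooccurrence_expected(7, 1.0, 1.0) == 7

    def test_same_variant_cooccurs_with_itself(self):
        rng = np.random.default_rng(3)
        df = null_cohort(rng, 500)
        res = cooccurrence_test(df, "v", "v")
        carriers_cases = int(((df.status == "case") & (df.v > 0)).sum())
        assert res["cases_both"] == carriers_cases

    def test_zero_cocarriers_p_is_one(self):
        df = pd.DataFrame({"status": ["case"] * 5 + ["control"] * 5,
                           "v1": [1, 0, 0, 0, 0, 0, 1, 0, 0, 0],
                           "v2": [0, 1, 0, 0, 0, 0, 0, 1, 0, 0]})
        res = cooccurrence_test(df, "v1", "v2")
        assert res["cases_both"] == 0 and res["controls_both"] == 0
        assert res["fisher_p"] == 1.0

    def test_null_calibration_is_subuniform(self):
        """With independent null variants the two-sided co-occurrence
        p-value rejects at most at the nominal rate (discrete test)."""
        rejections = 0
        n_reps = 200
        for seed in range(n_reps):
            rng = np.random.default_rng(seed)
            df = null_cohort(rng, n=1500, carrier_freq=0.15)
            df["w"] = (rng.random(len(df)) < 0.15).astype(float)
            res = cooccurrence_test(df, "v", "w", mode="two_sided")
            rejections += res["fisher_p"] <= 0.05
        band = 3 * math.sqrt(0.05 * 0.95 / n_reps)
        assert rejections / n_reps <= 0.05 + band


@pytest.fixture(scope="module")
def two_study_cohort():
    spec = SimulationSpec(seed=33,
                          cohorts={"A": (1200, 1200), "B": (2000, 1500)})
    pv = PlantedVariant(id="v", control_carrier_freq=0.04, cohort_or=2.0)
    return generate_cohort(spec, [pv])


class TestStratifiedAnalysis:
    def test_family_history_strata_pool_across_studies(self, two_study_cohort):
        out = stratified_analysis(two_study_cohort, "v", "family_history")
        meta = out[(out.study == "meta")]
        assert set(meta["stratum"]) == {"family_history=yes",
                                        "family_history=no"}

    def test_aggressiveness_strata_via_polytomous(self, two_study_cohort):
        out = stratified_analysis(two_study_cohort, "v", "aggressiveness")
        meta = out[out.study == "meta"].set_index("stratum")
        assert {"aggressive", "non-aggressive"} <= set(meta.index)
        for s in ("aggressive", "non-aggressive"):
            assert meta.loc[s, "ci_low"] <= meta.loc[s, "or_"] \
                <= meta.loc[s, "ci_high"]

    def test_zero_control_carriers_fall_back_to_fisher(self):
        rng = np.random.default_rng(7)
        n = 400
        df = pd.DataFrame({
            "study": ["A"] * n,
            "status": ["case"] * (n // 2) + ["control"] * (n // 2),
            "age": rng.normal(65, 8, n),
            "family_history": ["yes"] * n,
            "v": [1.0] * 10 + [0.0] * (n - 10)})  # carriers only in cases
        out = stratified_analysis(df, "v", "family_history")
        fisher = out[out.method.str.startswith("fisher")]
        assert len(fisher) == 1
        assert fisher.iloc[0]["stratum"] == "family_history=yes"
        assert 0 < fisher.iloc[0]["p"] <= 1

    def test_null_strata_near_unity(self):
        spec = SimulationSpec(seed=44, cohorts={"A": (2500, 2500)})
        pv = PlantedVariant(id="v", control_carrier_freq=0.08, cohort_or=1.0)
        df = generate_cohort(spec, [pv])
        out = stratified_analysis(df, "v", "aggressiveness")
        meta = out[out.study == "meta"]
        assert ((meta["ci_low"] <= 1.0) & (1.0 <= meta["ci_high"])).all()
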