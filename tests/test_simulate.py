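import warnings

import numpy as np
import pandas as pd
import pytest

from pedvar.filtering import segregating_families
from pedvar.pedigree import family_summary
from pedvar.qc import sample_qc, variant_qc
from pedvar.simulate import (AFFECTED_WEIGHTS, DX_AGE_WEIGHTS, WES_WEIGHTS,
                             PlantedVariant, QCFailureSpec, SimulationSpec,
                             gene_drop, generate_cohort, generate_families,
                             inject_qc_failures, plant_risk_variant,
                             simulate_study)


class TestGenerateFamilies:
    def test_deterministic_per_seed(self):
        spec = SimulationSpec(n_families=5, seed=42)
        a = generate_families(spec)
        b = generate_families(spec)
        assert [sorted(p.members) for p in a] == [sorted(p.members) for p in b]
        assert all(pa.members == pb.members for pa, pb in zip(a, b))

    def test_single_family_connected(self):
        ped, = generate_families(SimulationSpec(n_families=1, seed=0))
        assert len(ped.founders()) >= 1  # construction validates connectivity

    def test_bins_match_weights_within_binomial_bands(self):
        """75 families per replicate: every planted marginal falls
        inside the 95% binomial band of its target proportion."""
        spec = SimulationSpec(n_families=75, seed=11)
        peds = generate_families(spec)
        df = family_summary(peds).set_index(["characteristic", "bin"])
        checks = [("n_affected", {f"{lo} - {hi}": w for (lo, hi), w
                                  in AFFECTED_WEIGHTS.items()}),
                  ("mean_dx_age", {f"{lo} - {hi}": w for (lo, hi), w
                                   in DX_AGE_WEIGHTS.items()}),
                  ("n_wes", {str(k): w for k, w in WES_WEIGHTS.items()})]
        n = 75
        for char, weights in checks:
            total = sum(weights.values())
            for b, w in weights.items():
                p = w / total
                got = df.loc[(char, b), "n_families"]
                sd = np.sqrt(n * p * (1 - p))
                assert abs(got - n * p) <= 1.96 * sd + 1, (char, b, got)

    def test_infeasible_weights_rejected(self):
        spec = SimulationSpec(n_families=2, seed=0,
                              affected_weights={(3, 4): 0})
        with pytest.raises(ValueError, match="weights"):
            generate_families(spec)

    def test_three_families_non_european(self):
        peds = generate_families(SimulationSpec(n_families=75, seed=3))
        assert sum(p.ancestry != "european" for p in peds) == 3


class TestGeneDrop:
    def test_mendelian_consistent_everywhere(self, study20, rng):
        for ped in study20.peds[:5]:
            hap = gene_drop(ped, rng)
            for m in ped.members.values():
                if m.is_founder:
                    continue
                pat, mat = hap.labels[m.id]
                assert pat in hap.labels[m.father_id]
                assert mat in hap.labels[m.mother_id]

    def test_founder_label_conservation(self, study20, rng):
        ped = study20.peds[0]
        hap = gene_drop(ped, rng)
        founder_labels = {lab for f in ped.founders()
                          for lab in hap.labels[f.id]}
        assert len(founder_labels) == 2 * len(ped.founders())
        all_labels = {lab for pair in hap.labels.values() for lab in pair}
        assert all_labels <= founder_labels

    def test_transmission_frequency_is_half(self, three_branch_ped):
        """Across 10,000 drops, a founder haplotype reaches a
        grandchild through a fixed two-meiosis path with frequency
        1/4 +/- 3 SE, i.e. each meiosis transmits at 1/2."""
        rng = np.random.default_rng(5)
        n = 10_000
        hits = 0
        for _ in range(n):
            hap = gene_drop(three_branch_ped, rng)
            hits += "gf.0" in hap.labels["c2"]
        p = 0.25
        se = np.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) <= 3 * se


class TestPlantRiskVariant:
    def test_target_one_makes_all_affected_carriers(self, three_branch_ped):
        rng = np.random.default_rng(0)
        pv = PlantedVariant(id="v", target_carrier_fraction=1.0,
                            n_carrier_families=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = plant_risk_variant([three_branch_ped], pv, rng,
                                     ensure_wes_carrier=False)
        fam = res.truth["T1"]
        # the chosen haplotype is the one closest to covering all affected
        best = max(fam["fraction"], 0)
        assert fam["fraction"] == best
        carriers = {iid for (f, iid), g in res.variant.genotypes.items()
                    if g and f == "T1"}
        assert carriers == fam["carriers"]

    def test_truth_fraction_near_target(self, study20):
        rng = np.random.default_rng(1)
        pv = PlantedVariant(id="v", target_carrier_fraction=0.5,
                            n_carrier_families=6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = plant_risk_variant(study20.peds, pv, rng)
        for fam, t in res.truth.items():
            n_aff = len([m for m in study20.peds
                         if m.family_id == fam][0].affected_men())
            # closest achievable founder-haplotype fraction, never absurd
            assert 0 < t["fraction"] <= 1
            assert len(t["carriers"]) >= 1

    def test_roundtrip_segregating_family_count(self, study20):
        rng = np.random.default_rng(2)
        pv = PlantedVariant(id="v", n_carrier_families=4)
        res = plant_risk_variant(study20.peds, pv, rng)
        assert segregating_families(res.variant, study20.peds) == 4

    def test_too_many_families_rejected(self, three_branch_ped):
        pv = PlantedVariant(id="v", n_carrier_families=2)
        with pytest.raises(ValueError):
            plant_risk_variant([three_branch_ped], pv,
                               np.random.default_rng(0))


class TestGenerateCohort:
    def test_null_or_gives_equal_frequencies(self):
        spec = SimulationSpec(seed=9, cohorts={"S": (4000, 4000)})
        pv = PlantedVariant(id="v", cohort_or=1.0, control_carrier_freq=0.05)
        df = generate_cohort(spec, [pv])
        f_case = df.loc[df.status == "case", "v"].mean()
        f_ctrl = df.loc[df.status == "control", "v"].mean()
        se = np.sqrt(2 * 0.05 * 0.95 / 4000)
        assert abs(f_case - f_ctrl) < 3 * se

    def test_same_seed_identical(self):
        spec = SimulationSpec(seed=4, cohorts={"S": (500, 500)})
        pv = PlantedVariant(id="v", control_carrier_freq=0.02, cohort_or=2.0)
        pd.testing.assert_frame_equal(generate_cohort(spec, [pv]),
                                      generate_cohort(spec, [pv]))

    def test_rare_variant_warns(self):
        spec = SimulationSpec(seed=4, cohorts={"S": (200, 200)})
        pv = PlantedVariant(id="v", control_carrier_freq=0.001)
        with pytest.warns(UserWarning, match="expected carrier"):
            generate_cohort(spec, [pv])

    def test_marginals_roughly_match_spec(self):
        spec = SimulationSpec(seed=12)
        df = generate_cohort(spec, [])
        assert sorted(df["study"].unique()) == ["FHCRC", "PLCO"]
        fh = df.groupby("status")["family_history"].apply(
            lambda s: (s == "yes").mean())
        assert fh["case"] == pytest.approx(0.14, abs=0.02)
        assert fh["control"] == pytest.approx(0.08, abs=0.02)
        agg = (df.loc[df.status == "case", "aggressiveness"]
               == "aggressive").mean()
        assert agg == pytest.approx(0.20, abs=0.02)
        assert (df.loc[df.status == "control", "aggressiveness"]
                == "control").all()


class TestInjectQCFailures:
    @pytest.fixture
    def clean_matrix(self):
        """60 variants x (200 family + 300 control) samples; every
        variant passes every QC rule before degradation."""
        rng = np.random.default_rng(8)
        n_fam_samples, n_controls, n_var = 200, 300, 60
        samples = [f"fam_s{i}" for i in range(n_fam_samples)] + \
                  [f"ctl_s{i}" for i in range(n_controls)]
        info = pd.DataFrame({
            "is_control": [False] * n_fam_samples + [True] * n_controls,
            "family_id": [f"F{i // 5}" for i in range(n_fam_samples)]
                         + [None] * n_controls}, index=samples)
        m = pd.DataFrame(0.0, index=samples, columns=[f"v{j}" for j in range(n_var)])
        for j in range(n_var):
            fams = rng.choice(40, size=4, replace=False)
            for f in fams:
                m.iloc[int(f) * 5, j] = 1.0  # one carrier in each of 4 families
            ctl = rng.choice(n_controls, size=2, replace=False)
            for c in ctl:
                m.iloc[n_fam_samples + int(c), j] = 1.0  # 2/300 < 2%
        return m, info

    def test_planted_failures_recovered_exactly(self, clean_matrix):
        m, info = clean_matrix
        rng = np.random.default_rng(3)
        degraded, truth = inject_qc_failures(m, info, QCFailureSpec(), rng)
        kept, sample_report = sample_qc(degraded)
        assert sorted(sample_report["sample"]) == truth["samples"]
        assert len(sample_report) == 20
        kept2, var_report = variant_qc(kept, info)
        assert len(var_report) == 27
        by_rule = var_report.groupby("rule")["variant"].apply(
            lambda s: sorted(s)).to_dict()
        assert by_rule["call_rate"] == truth["call_rate"]
        assert by_rule["control_freq"] == truth["control_freq"]
        assert by_rule["family_count"] == truth["few_families"]

    def test_zero_failures_removes_nothing(self, clean_matrix):
        m, info = clean_matrix
        spec = QCFailureSpec(n_sample_failures=0, n_variant_call_rate=0,
                             n_variant_control_freq=0,
                             n_variant_few_families=0)
        degraded, _ = inject_qc_failures(m, info, spec,
                                         np.random.default_rng(0))
        kept, rep = sample_qc(degraded)
        assert rep.empty
        kept2, vrep = variant_qc(kept, info)
        assert vrep.empty


def test_simulate_study_is_deterministic():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = simulate_study(SimulationSpec(n_families=8, seed=5))
        b = simulate_study(SimulationSpec(n_families=8, seed=5))
    assert [v.vid for v in a.variants] == [v.vid for v in b.variants]
    assert a.variants[0].genotypes == b.variants[0].genotypes
    pd.testing.assert_frame_equal(a.cohort, b.cohort)
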