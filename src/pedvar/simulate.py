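"""Seeded generators for pedigrees, founder haplotypes, planted risk
variants, reference panels, and case-control cohorts.

The defaults reproduce the study conditions the pipeline was designed
for: 75 multiplex families with the published family-size, diagnosis-
age and sequenced-case distributions; 11 reference populations;
planted risk variants at <= 2% population frequency with affected-
carrier fractions in the 40-65% range; and two cohorts sized like the
FHCRC (1,265 cases / 1,230 controls) and PLCO (4,222 / 2,899) studies
with ~14%/~8% first-degree family history in cases/controls and ~20%
aggressive disease among cases.

Penetrance is implicit: a planted variant rides one founder haplotype
chosen so its descendant affected-carrier fraction is closest to the
target, leaving the affection structure of the family untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .carriers import HaplotypeMap
from .filtering import ReferencePanel, VariantRecord
from .pedigree import Individual, Pedigree, select_wes_candidates

__all__ = [
    "SimulationSpec",
    "PlantedVariant",
    "generate_families",
    "gene_drop",
    "plant_risk_variant",
    "generate_reference_panel",
    "generate_cohort",
    "inject_qc_failures",
    "simulate_study",
]

# Family marginals: (bin, number of families out of 75)
AFFECTED_WEIGHTS = {(3, 4): 5, (5, 6): 30, (7, 8): 22, (9, 10): 15, (11, 18): 3}
DX_AGE_WEIGHTS = {(50, 54.9): 3, (55, 59.9): 7, (60, 64.9): 30,
                  (65, 69.9): 28, (70, 79.5): 7}
WES_WEIGHTS = {1: 44, 2: 2, 3: 13, 4: 8, 5: 7, 6: 1}

REFERENCE_POPULATIONS = [
    "ESP_EA", "ESP_AA", "KG_EUR", "KG_AFR", "KG_AMR", "KG_EAS", "KG_SAS",
    "KG_ALL", "KG_EX_EUR", "KG_EX_AFR", "KG_EX_ALL"]


@dataclass
class PlantedVariant:
    """Specification of one simulated risk variant."""

    id: str
    chrom: str = "1"
    pos: int = 1
    ref: str = "A"
    alt: str = "T"
    gene: str = "GENE"
    consequence: str = "missense"
    sift: tuple[str | None, float | None] = ("deleterious", 0.01)
    polyphen: tuple[str | None, float | None] = ("probably", 0.99)
    population_af: dict[str, float] = dc_field(default_factory=dict)
    n_carrier_families: int = 3
    target_carrier_fraction: float | None = None  # drawn U[0.40, 0.65] if None
    control_carrier_freq: float = 0.01
    cohort_or: float = 1.0

    def __post_init__(self) -> None:
        if self.cohort_or <= 0:
            raise ValueError("odds ratio must be positive")
        if self.target_carrier_fraction is not None and not (
                0 < self.target_carrier_fraction <= 1):
            raise ValueError("target carrier fraction must be in (0, 1]")


@dataclass
class SimulationSpec:
    """All tunable conditions for a synthetic study."""

    n_families: int = 75
    affected_weights: dict = dc_field(default_factory=lambda: dict(AFFECTED_WEIGHTS))
    dx_age_weights: dict = dc_field(default_factory=lambda: dict(DX_AGE_WEIGHTS))
    wes_weights: dict = dc_field(default_factory=lambda: dict(WES_WEIGHTS))
    n_non_european: int = 3
    reference_populations: list[str] = dc_field(
        default_factory=lambda: list(REFERENCE_POPULATIONS))
    planted_variants: list[PlantedVariant] = dc_field(default_factory=list)
    cohorts: dict[str, tuple[int, int]] = dc_field(
        default_factory=lambda: {"FHCRC": (1265, 1230), "PLCO": (4222, 2899)})
    age_mean: float = 65.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (40.0, 90.0)
    family_history_case: float = 0.14
    family_history_control: float = 0.08
    aggressive_fraction: float = 0.20
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.family_history_case, self.family_history_control,
                  self.aggressive_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_families <= 0:
            raise ValueError("n_families must be positive")


def _draw_bin(rng: np.random.Generator, weights: dict):
    bins = list(weights)
    w = np.array([weights[b] for b in bins], dtype=float)
    if w.sum() <= 0 or (w < 0).any():
        raise ValueError("infeasible bin weights")
    return bins[rng.choice(len(bins), p=w / w.sum())]


# ------------------------------------------------------------ families

def generate_families(spec: SimulationSpec,
                      rng: np.random.Generator | None = None) -> list[Pedigree]:
    """Generate multi-generation pedigrees whose binned summaries match
    the spec's marginal weights in expectation.  Deterministic per
    seed."""
    rng = rng or np.random.default_rng(spec.seed)
    peds = []
    non_eur = set(rng.choice(spec.n_families,
                             size=min(spec.n_non_european, spec.n_families),
                             replace=False))
    for i in range(spec.n_families):
        lo, hi = _draw_bin(rng, spec.affected_weights)
        n_affected = int(rng.integers(lo, hi + 1))
        n_wes = min(_draw_bin(rng, spec.wes_weights), n_affected)
        alo, ahi = _draw_bin(rng, spec.dx_age_weights)
        mean_age = float(rng.uniform(alo, ahi))
        ancestry = "other" if i in non_eur else "european"
        peds.append(_build_family(f"F{i + 1:03d}", n_affected, n_wes,
                                  mean_age, spec, rng, ancestry))
    return peds


def _build_family(fam_id: str, n_affected: int, n_wes: int, mean_age: float,
                  spec: SimulationSpec, rng: np.random.Generator,
                  ancestry: str) -> Pedigree:
    """Three-generation pedigree: a founding couple, their married
    children, and grandchildren — enough blood males to host the
    affected set, with branch structure that yields second-degree and
    third-degree relative pairs among sequenced cases."""
    members: dict[str, Individual] = {}
    nid = iter(range(1, 10_000))

    def add(sex, father=None, mother=None):
        iid = f"{fam_id}-{next(nid):03d}"
        members[iid] = Individual(id=iid, father_id=father, mother_id=mother,
                                  sex=sex)
        return iid

    gf = add("male")
    gm = add("female")
    n_branches = int(rng.integers(2, 5))
    blood_males: list[str] = [gf]
    gen2_parents = []
    for _ in range(n_branches):
        sex = "male" if rng.random() < 0.5 else "female"
        child = add(sex, gf, gm)
        if sex == "male":
            blood_males.append(child)
        spouse = add("female" if sex == "male" else "male")
        gen2_parents.append((child, spouse) if sex == "male"
                            else (spouse, child))
    for father, mother in gen2_parents:
        for _ in range(int(rng.integers(2, 5))):
            sex = "male" if rng.random() < 0.5 else "female"
            child = add(sex, father, mother)
            if sex == "male":
                blood_males.append(child)
    # top up grandchildren until the affected set fits
    while len(blood_males) < n_affected:
        father, mother = gen2_parents[int(rng.integers(len(gen2_parents)))]
        child = add("male", father, mother)
        blood_males.append(child)

    order = list(rng.permutation(len(blood_males)))
    affected_ids = [blood_males[j] for j in order[:n_affected]]
    raw = rng.normal(0.0, 6.0, size=n_affected)
    ages = np.clip(mean_age + (raw - raw.mean()), *spec.age_range)
    for iid, age in zip(affected_ids, ages):
        m = members[iid]
        members[iid] = Individual(
            id=iid, father_id=m.father_id, mother_id=m.mother_id, sex="male",
            affected=True, dx_age=round(float(age), 1),
            aggressive=bool(rng.random() < spec.aggressive_fraction),
            vital="deceased" if rng.random() < 0.3 else "alive",
            dna_available=True)
    ped = Pedigree(fam_id, members.values(), ancestry=ancestry)
    for iid in select_wes_candidates(ped, n_wes):
        ped = ped.update_member(iid, wes=True)
    return ped


# ----------------------------------------------------------- gene drop

def gene_drop(ped: Pedigree, rng: np.random.Generator) -> HaplotypeMap:
    """Drop founder haplotypes through the pedigree: each founder
    contributes two uniquely labelled haplotypes and every non-founder
    inherits one label from each parent.  Mendelian-consistent by
    construction (no recombination at a single variant locus)."""
    labels: dict[str, tuple[str, str]] = {}
    ids = sorted(ped.members, key=lambda i: (ped.depth(i), i))
    for iid in ids:
        ind = ped.members[iid]
        if ind.is_founder:
            labels[iid] = (f"{iid}.0", f"{iid}.1")
        else:
            pat = labels[ind.father_id][int(rng.integers(2))]
            mat = labels[ind.mother_id][int(rng.integers(2))]
            labels[iid] = (pat, mat)
    return HaplotypeMap(ped.family_id, labels,
                        affected_roster=sorted(m.id for m in ped.affected_men()))


# -------------------------------------------------------- risk planting

@dataclass
class PlantResult:
    variant: VariantRecord
    hap_maps: dict[str, HaplotypeMap]  # family -> locus haplotype map
    truth: dict[str, dict]  # family -> {haplotype, carriers, fraction}


def plant_risk_variant(peds: list[Pedigree], pv: PlantedVariant,
                       rng: np.random.Generator,
                       ensure_wes_carrier: bool = True) -> PlantResult:
    """Plant ``pv`` in ``pv.n_carrier_families`` randomly chosen
    families.

    Within each carrier family a fresh gene drop is performed and the
    alternate allele assigned to the founder haplotype whose affected-
    carrier fraction is closest to the target (drawn from U[0.40, 0.65]
    per family when unspecified).  With ``ensure_wes_carrier`` the
    choice is restricted to haplotypes carried by at least one
    sequenced affected man, so planting in k families guarantees k
    segregating families.  Genotypes are emitted for every member of
    every family (identity-by-descent: carriers are heterozygous).
    """
    if pv.n_carrier_families > len(peds):
        raise ValueError("more carrier families requested than families exist")
    chosen = {peds[j].family_id
              for j in rng.choice(len(peds), size=pv.n_carrier_families,
                                  replace=False)}
    genotypes: dict[tuple[str, str], int | None] = {}
    hap_maps: dict[str, HaplotypeMap] = {}
    truth: dict[str, dict] = {}
    for ped in peds:
        hap = gene_drop(ped, rng)
        hap_maps[ped.family_id] = hap
        if ped.family_id not in chosen:
            for iid in ped.members:
                genotypes[(ped.family_id, iid)] = 0
            continue
        target = (pv.target_carrier_fraction
                  if pv.target_carrier_fraction is not None
                  else float(rng.uniform(0.40, 0.65)))
        roster = hap.affected_roster
        wes_ids = {m.id for m in ped.wes_cases()}
        frac_by_label: dict[str, float] = {}
        wes_hit: dict[str, bool] = {}
        all_labels = sorted({lab for pair in hap.labels.values() for lab in pair})
        for lab in all_labels:
            carriers = [iid for iid in roster if lab in hap.labels[iid]]
            frac_by_label[lab] = len(carriers) / len(roster)
            wes_hit[lab] = any(iid in wes_ids for iid in carriers)
        pool = ([l for l in all_labels if wes_hit[l]]
                if ensure_wes_carrier and any(wes_hit.values()) else all_labels)
        label = min(pool, key=lambda l: (abs(frac_by_label[l] - target), l))
        if abs(frac_by_label[label] - target) > 0.25:
            warnings.warn(
                f"family {ped.family_id}: no founder haplotype within 0.25 of "
                f"the target carrier fraction {target:.2f}; using "
                f"{frac_by_label[label]:.2f}", stacklevel=2)
        carrier_set = {iid for iid, pair in hap.labels.items() if label in pair}
        for iid in ped.members:
            genotypes[(ped.family_id, iid)] = 1 if iid in carrier_set else 0
        truth[ped.family_id] = {
            "haplotype": label,
            "carriers": carrier_set,
            "fraction": frac_by_label[label],
        }
    variant = VariantRecord(
        chrom=pv.chrom, pos=pv.pos, ref=pv.ref, alt=pv.alt, gene=pv.gene,
        consequence=pv.consequence, sift=pv.sift, polyphen=pv.polyphen,
        genotypes=genotypes)
    return PlantResult(variant, hap_maps, truth)


# ------------------------------------------------------ reference panel

def generate_reference_panel(variants: list[PlantedVariant],
                             populations: list[str] | None = None,
                             ) -> ReferencePanel:
    pops = populations or list(REFERENCE_POPULATIONS)
    freqs = {}
    for pv in variants:
        vid = f"{pv.chrom}:{pv.pos}:{pv.ref}:{pv.alt}"
        freqs[vid] = dict(pv.population_af)
    return ReferencePanel(populations=pops, freqs=freqs)


# -------------------------------------------------------------- cohorts

def generate_cohort(spec: SimulationSpec, variants: list[PlantedVariant],
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Case-control cohort tables for every study in the spec.

    Carrier status is Bernoulli with the control carrier frequency in
    controls and the odds-ratio-shifted frequency in cases, so the
    dominant-model odds ratio equals the planted value in expectation.
    Variants are independent across subjects and of age.
    """
    rng = rng or np.random.default_rng(spec.seed)
    frames = []
    for study, (n_cases, n_controls) in spec.cohorts.items():
        n = n_cases + n_controls
        status = np.array(["case"] * n_cases + ["control"] * n_controls)
        lo, hi = spec.age_range
        age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), lo, hi)
        fh_p = np.where(status == "case", spec.family_history_case,
                        spec.family_history_control)
        fh = np.where(rng.random(n) < fh_p, "yes", "no")
        aggressive = np.where(
            status == "control", "control",
            np.where(rng.random(n) < spec.aggressive_fraction,
                     "aggressive", "non-aggressive"))
        df = pd.DataFrame({
            "subject_id": [f"{study}-{i + 1:05d}" for i in range(n)],
            "study": study, "status": status, "age": np.round(age, 1),
            "family_history": fh, "aggressiveness": aggressive})
        for pv in variants:
            p0 = pv.control_carrier_freq
            if p0 * min(n_cases, n_controls) < 1:
                warnings.warn(
                    f"{pv.id}: fewer than one expected carrier in {study}",
                    stacklevel=2)
            odds1 = pv.cohort_or * p0 / (1.0 - p0)
            p1 = odds1 / (1.0 + odds1)
            p = np.where(status == "case", p1, p0)
            df[pv.id] = (rng.random(n) < p).astype(float)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------- QC failures

@dataclass
class QCFailureSpec:
    n_sample_failures: int = 20
    n_variant_call_rate: int = 12
    n_variant_control_freq: int = 9
    n_variant_few_families: int = 6
    call_rate_min: float = 0.70
    control_freq_max: float = 0.02
    fam_min: int = 3


def inject_qc_failures(matrix: pd.DataFrame, sample_info: pd.DataFrame,
                       fail_spec: QCFailureSpec,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, dict]:
    """Degrade a genotype matrix to plant known QC failures.

    Masks calls to push chosen samples and variants below the call-rate
    threshold, inflates chosen variants' control carrier frequencies
    above the limit, and zeroes family carriers of chosen variants so
    they are present in fewer than ``fam_min`` families.  Returns the
    degraded copy and the planted truth labels.
    """
    m = matrix.copy().astype(float)
    info = sample_info.loc[m.index]
    fs = fail_spec
    n_var = m.shape[1]
    total_planted = (fs.n_variant_call_rate + fs.n_variant_control_freq
                     + fs.n_variant_few_families)
    if total_planted > n_var:
        raise ValueError("more planted variant failures than variants")
    var_pick = list(rng.choice(n_var, size=total_planted, replace=False))
    v_call = [m.columns[i] for i in var_pick[:fs.n_variant_call_rate]]
    v_freq = [m.columns[i] for i in
              var_pick[fs.n_variant_call_rate:
                       fs.n_variant_call_rate + fs.n_variant_control_freq]]
    v_fam = [m.columns[i] for i in
             var_pick[fs.n_variant_call_rate + fs.n_variant_control_freq:]]

    clean_cols = [c for c in m.columns if c not in set(v_call)]
    # planted failures must not cascade: failing samples are drawn from
    # controls and non-carrier family members, and only their
    # non-carrier calls are masked, so removing them never changes a
    # clean variant's carrier-family count or control frequency.
    is_control = info["is_control"].fillna(False).astype(bool)
    carries_clean = (m[clean_cols] > 0).any(axis=1)
    eligible = [s for s in m.index
                if is_control[s] or not carries_clean[s]]
    if fs.n_sample_failures > len(eligible):
        raise ValueError("not enough non-carrier samples to plant failures")
    sample_pick = [eligible[i] for i in
                   rng.choice(len(eligible), size=fs.n_sample_failures,
                              replace=False)]
    for s in sample_pick:
        k = int(np.ceil((1.0 - fs.call_rate_min + 0.05) * n_var))
        zero_cols = [c for c in clean_cols if not m.loc[s, c] > 0]
        cols = rng.choice(len(zero_cols), size=min(k, len(zero_cols)),
                          replace=False)
        m.loc[s, [zero_cols[j] for j in cols]] = np.nan

    good_samples = [s for s in m.index if s not in set(sample_pick)]
    for v in v_call:
        k = int(np.ceil((1.0 - fs.call_rate_min + 0.05) * len(m)))
        idx = rng.choice(len(good_samples), size=min(k, len(good_samples)),
                         replace=False)
        m.loc[[good_samples[j] for j in idx], v] = np.nan

    controls = info.index[is_control]
    surviving = [c for c in controls if c not in set(sample_pick)]
    for v in v_freq:
        want = int(np.ceil((fs.control_freq_max + 0.01) * len(controls)))
        picks = rng.choice(len(surviving), size=min(want, len(surviving)),
                           replace=False)
        m.loc[[surviving[j] for j in picks], v] = 1.0

    fam = info["family_id"]
    for v in v_fam:
        carriers = m.index[(m[v] > 0).fillna(False)]
        carrier_fams = sorted(fam.loc[carriers].dropna().unique())
        for f in carrier_fams[max(0, fs.fam_min - 1 - 1) + 1:]:
            # zero out carriers beyond the first (fam_min - 1) families
            in_fam = fam == f
            m.loc[in_fam & (m[v] > 0).fillna(False), v] = 0.0
        # re-check: keep at most fam_min - 1 carrier families
    truth = {"samples": sorted(sample_pick), "call_rate": sorted(v_call),
             "control_freq": sorted(v_freq), "few_families": sorted(v_fam)}
    return m, truth


# ----------------------------------------------------- whole-study glue

@dataclass
class StudyData:
    """Everything one synthetic study produces."""

    peds: list[Pedigree]
    variants: list[VariantRecord]
    panel: ReferencePanel
    hap_maps: dict[str, dict[str, HaplotypeMap]]  # vid -> family -> map
    planted: list[PlantedVariant]
    truth: dict[str, dict]
    cohort: pd.DataFrame


def default_planted_variants(n_passing: int = 10,
                             rng: np.random.Generator | None = None,
                             ) -> list[PlantedVariant]:
    """A small panel of plausible risk variants: rare everywhere,
    damaging, segregating in several families, odds ratios 1.5-4."""
    rng = rng or np.random.default_rng(0)
    out = []
    for i in range(n_passing):
        out.append(PlantedVariant(
            id=f"risk{i + 1:02d}", chrom=str((i % 22) + 1),
            pos=1_000_000 + i * 1000, ref="A", alt="G",
            gene=f"RGENE{i + 1}",
            consequence="stop_gained" if i % 3 == 0 else "missense",
            sift=(None, None) if i % 3 == 0 else ("deleterious", 0.01),
            polyphen=(None, None) if i % 3 == 0 else ("probably", 0.98),
            population_af={"ESP_EA": 0.0005, "KG_EUR": 0.0005},
            n_carrier_families=int(rng.integers(3, 8)),
            control_carrier_freq=float(rng.uniform(0.005, 0.02)),
            cohort_or=float(rng.uniform(1.5, 4.0))))
    return out


def background_variants(n: int, rng: np.random.Generator,
                        peds: list[Pedigree]) -> tuple[list[VariantRecord], dict]:
    """Variants constructed to fail specific cascade stages: common in
    a reference population, benign/tolerated missense, or too rarely
    segregating.  Returns the records plus per-variant expected fate."""
    fates = ["popfreq", "impact", "enrichment"]
    records, fate_of = [], {}
    for i in range(n):
        fate = fates[i % 3]
        consequence, sift, poly = "missense", ("deleterious", 0.02), ("possibly", 0.7)
        af = {p: 0.001 for p in ("ESP_EA", "KG_EUR")}
        if fate == "popfreq":
            af["KG_AFR"] = 0.05
        elif fate == "impact":
            sift, poly = ("tolerated", 0.6), ("benign", 0.1)
        genotypes: dict[tuple[str, str], int | None] = {}
        carrier_fams = []
        if fate == "enrichment":
            # carried by sequenced cases in only 1-2 families
            k = 1 + i % 2
            carrier_fams = [peds[int(j)].family_id
                            for j in rng.choice(len(peds), size=k, replace=False)]
        for ped in peds:
            for iid in ped.members:
                genotypes[(ped.family_id, iid)] = 0
            if ped.family_id in carrier_fams:
                wes = ped.wes_cases()
                genotypes[(ped.family_id, wes[0].id)] = 1
        rec = VariantRecord(chrom="9", pos=5_000_000 + i, ref="C", alt="T",
                            gene=f"BG{i}", consequence=consequence, sift=sift,
                            polyphen=poly, genotypes=genotypes)
        records.append(rec)
        fate_of[rec.vid] = fate
    return records, {"fate": fate_of, "panel_af": {r.vid: dict(
        {"ESP_EA": 0.001, "KG_EUR": 0.001},
        **({"KG_AFR": 0.05} if fate_of[r.vid] == "popfreq" else {}))
        for r in records}}


def simulate_study(spec: SimulationSpec, n_background: int = 30) -> StudyData:
    """Generate a complete synthetic study: families, planted risk
    variants with their haplotype truth, stage-failing background
    variants, the reference panel, and the case-control cohorts."""
    rng = np.random.default_rng(spec.seed)
    peds = generate_families(spec, rng)
    planted = spec.planted_variants or default_planted_variants(rng=rng)
    variants, hap_maps, truth = [], {}, {}
    for pv in planted:
        res = plant_risk_variant(peds, pv, rng)
        variants.append(res.variant)
        hap_maps[res.variant.vid] = res.hap_maps
        truth[res.variant.vid] = res.truth
    bg, bg_truth = background_variants(n_background, rng, peds)
    variants.extend(bg)
    panel = generate_reference_panel(planted)
    panel.freqs.update(bg_truth["panel_af"])
    cohort = generate_cohort(spec, planted, rng)
    cohort = cohort.rename(columns={pv.id: _vid(pv) for pv in planted})
    truth["background"] = bg_truth["fate"]
    return StudyData(peds, variants, panel, hap_maps, planted, truth, cohort)


def _vid(pv: PlantedVariant) -> str:
    return f"{pv.chrom}:{pv.pos}:{pv.ref}:{pv.alt}"
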