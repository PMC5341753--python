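"""Orchestration of the full cascade and the validation arm.

``run_cascade`` executes population-frequency filter → protein-impact
filter → enrichment (frequency ratio + segregation) → haplotype-based
carrier inference → four-criterion selection, and reports per-stage
variant counts.  ``run_validation`` runs the case-control statistics
(per-study dominant-model regression, fixed-effect meta-analysis,
stratified analyses, risk score, co-occurrence) on a cohort table.
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import assoc
from .carriers import (HaplotypeMap, average_carrier_frequency,
                       candidate_haplotypes, family_carrier_bounds,
                       genotyped_carrier_counts)
from .filtering import (ReferencePanel, VariantRecord, enrichment_stage,
                        impact_filter, population_frequency_filter)
from .pedigree import Pedigree, _phenotype_tier
from .selection import SelectionCriteria, select_candidates

__all__ = ["RunConfig", "CascadeResult", "run_cascade", "run_validation",
           "proband_of"]


@dataclass
class RunConfig:
    """Thresholds and policy switches for one run."""

    popfreq_threshold: float = 0.02
    ratio_min: float = 2.0
    fam_min: int = 3
    ratio_denominator: str = "max"  # {max, min, <population label>}
    drop_inconsistent_families: bool = False
    fisher_mode: str = "point"
    alpha: float = 0.05
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    seed: int = 0

    def manifest(self) -> dict:
        d = asdict(self)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d,
                "config_sha256": hashlib.sha256(blob.encode()).hexdigest()}


@dataclass
class CascadeResult:
    stage_counts: dict
    enrichment: pd.DataFrame
    metrics: pd.DataFrame  # per-variant selection metrics + flags
    selected: list[str]
    manifest: dict


def proband_of(ped: Pedigree) -> str | None:
    """The single sequenced affected man representing the family in the
    enrichment comparison, ranked by the sequencing priority rule."""
    wes = ped.wes_cases()
    if not wes:
        return None
    return min(wes, key=lambda m: (_phenotype_tier(m), m.id)).id


def run_cascade(variants: list[VariantRecord], panel: ReferencePanel,
                peds: list[Pedigree],
                hap_maps: dict[str, dict[str, HaplotypeMap]] | dict[str, HaplotypeMap],
                config: RunConfig = RunConfig()) -> CascadeResult:
    """Run the prioritization cascade.

    ``hap_maps`` maps variant id -> family -> HaplotypeMap (per-locus
    maps) or family -> HaplotypeMap (one shared map per family).
    """
    counts = {"input": len(variants)}
    kept, _ = population_frequency_filter(variants, panel,
                                          config.popfreq_threshold)
    counts["after_popfreq"] = len(kept)
    kept, _ = impact_filter(kept)
    counts["after_impact"] = len(kept)

    eur = [p for p in peds if p.ancestry == "european"]
    probands = [(p.family_id, proband_of(p)) for p in eur
                if proband_of(p) is not None]
    if kept:
        retained, all_res = enrichment_stage(
            kept, panel, peds, probands, ratio_min=config.ratio_min,
            fam_min=config.fam_min, denominator=config.ratio_denominator)
    else:
        retained, all_res = [], []
    counts["after_enrichment"] = len(retained)
    enr_df = pd.DataFrame([vars(r) for r in all_res])

    by_vid = {v.vid: v for v in variants}
    rows = []
    for res in retained:
        v = by_vid[res.variant_id]
        fam_maps = hap_maps.get(res.variant_id, hap_maps)
        bounds = []
        for ped in peds:
            has_carrier = any(
                (v.genotypes.get((ped.family_id, m.id)) or 0) > 0
                for m in ped.wes_cases())
            if not has_carrier:
                continue
            hap = fam_maps.get(ped.family_id)
            if hap is None:
                warnings.warn(f"no haplotype map for family {ped.family_id}; "
                              f"skipped for {v.vid}", stacklevel=2)
                continue
            cand, status = candidate_haplotypes(ped, v, hap)
            if status == "inconsistent" and config.drop_inconsistent_families:
                continue
            bounds.append(family_carrier_bounds(ped, cand, hap, status))
        if not bounds:
            continue
        summ = average_carrier_frequency(v.vid, bounds)
        n_aff, n_unaff = genotyped_carrier_counts(v, peds)
        rows.append({
            "variant_id": v.vid, "gene": v.gene,
            "n_segregating_families": res.n_segregating_families,
            "frequency_ratio": res.frequency_ratio,
            "min_avg": round(summ.min_avg, 1),
            "max_avg": round(summ.max_avg, 1),
            "n_affected_carriers": n_aff,
            "n_unaffected_carriers": n_unaff,
        })
    metrics = pd.DataFrame(rows, columns=[
        "variant_id", "gene", "n_segregating_families", "frequency_ratio",
        "min_avg", "max_avg", "n_affected_carriers", "n_unaffected_carriers"])
    if len(metrics):
        metrics = select_candidates(metrics, config.criteria)
        selected = sorted(metrics.loc[metrics["selected"], "variant_id"])
    else:
        selected = []
    counts["selected"] = len(selected)
    manifest = config.manifest()
    manifest["stage_counts"] = counts
    return CascadeResult(counts, enr_df, metrics, selected, manifest)


def run_validation(cohort: pd.DataFrame, variant_ids: list[str],
                   config: RunConfig = RunConfig(),
                   risk_score_variants: list[str] | None = None,
                   cooccur_pair: tuple[str, str] | None = None) -> dict:
    """Case-control validation of candidate variants.

    Returns a dict of result tables: ``association`` (per-study and
    meta rows with a ``confirmed`` flag — risk-increasing and
    significant at alpha), ``by_family_history``, ``by_aggressiveness``,
    ``risk_score``, and ``cooccurrence``.
    """
    studies = sorted(cohort["study"].unique())
    absent = [v for v in variant_ids if v not in cohort.columns]
    if absent:
        warnings.warn(
            f"{len(absent)} candidate variants lack cohort genotypes and are "
            "skipped", stacklevel=2)
        variant_ids = [v for v in variant_ids if v in cohort.columns]
    rows = []
    for vid in variant_ids:
        per_study = []
        for s in studies:
            sub = cohort[cohort["study"] == s]
            try:
                r = assoc.logistic_dominant(sub, vid, study=s)
                per_study.append(r)
                rows.append(r)
            except assoc.SeparationError as e:
                warnings.warn(str(e), stacklevel=2)
        if len(per_study) > 1:
            try:
                rows.append(assoc.meta_fixed(per_study))
            except assoc.SeparationError as e:
                warnings.warn(str(e), stacklevel=2)
    adf = pd.DataFrame([vars(r) for r in rows])
    if len(adf):
        pooled = ((adf["study"] == "meta") if (adf["study"] == "meta").any()
                  else pd.Series(True, index=adf.index))
        adf["confirmed"] = pooled & (adf["or_"] > 1.0) & (adf["p"] < config.alpha)
    confirmed = sorted(adf.loc[adf.get("confirmed", pd.Series(dtype=bool)).fillna(False),
                               "variant"].unique()) if len(adf) else []

    out: dict[str, object] = {"association": adf, "confirmed": confirmed}
    strat_targets = confirmed or variant_ids[:1]
    fh, agg = [], []
    for vid in strat_targets:
        try:
            fh.append(assoc.stratified_analysis(
                cohort, vid, "family_history", fisher_mode=config.fisher_mode))
        except (ValueError, assoc.SeparationError) as e:
            warnings.warn(f"{vid} family-history stratification skipped: {e}",
                          stacklevel=2)
        try:
            agg.append(assoc.stratified_analysis(cohort, vid, "aggressiveness"))
        except (ValueError, assoc.SeparationError) as e:
            warnings.warn(f"{vid} aggressiveness stratification skipped: {e}",
                          stacklevel=2)
    out["by_family_history"] = (pd.concat(fh, ignore_index=True)
                                if fh else pd.DataFrame())
    out["by_aggressiveness"] = (pd.concat(agg, ignore_index=True)
                                if agg else pd.DataFrame())

    rs_vars = risk_score_variants or confirmed
    if len(rs_vars) >= 1:
        out["risk_score"] = assoc.genetic_risk_score(cohort, list(rs_vars))
    else:
        out["risk_score"] = pd.DataFrame()
    pair = cooccur_pair or (tuple(confirmed[:2]) if len(confirmed) >= 2 else None)
    if pair:
        out["cooccurrence"] = assoc.cooccurrence_test(
            cohort, pair[0], pair[1], mode=config.fisher_mode)
    else:
        out["cooccurrence"] = {}
    return out


def _json_default(o):
    if isinstance(o, float) and math.isinf(o):
        return "inf"
    raise TypeError(str(type(o)))
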