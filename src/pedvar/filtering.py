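"""Upper half of the prioritization cascade.

Filters annotated exome variants by reference-panel population
frequency and predicted protein impact, then computes the enrichment
statistics: the *frequency ratio* (proband allele frequency over the
European reference-panel frequency) and the number of families in which
a variant segregates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .pedigree import Pedigree

__all__ = [
    "VariantRecord",
    "ReferencePanel",
    "EnrichmentResult",
    "HIGH_IMPACT",
    "population_frequency_filter",
    "impact_filter",
    "observed_frequency",
    "frequency_ratio",
    "segregating_families",
    "enrichment_stage",
]

HIGH_IMPACT = frozenset(
    {"stop_gained", "stop_lost", "start_lost", "frameshift", "splice_site"})
CONSEQUENCES = HIGH_IMPACT | {"missense", "other"}


@dataclass
class VariantRecord:
    """One annotated variant with per-sample genotypes.

    ``genotypes`` maps ``(family_id, individual_id)`` to the alternate
    allele count {0, 1, 2} or None for a missing call.  ``sift`` /
    ``polyphen`` are (prediction, score) pairs; nonsense variants have
    no predictions (None, None).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    sift: tuple[str | None, float | None] = (None, None)
    polyphen: tuple[str | None, float | None] = (None, None)
    genotypes: dict[tuple[str, str], int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles are identical")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        for name, (_, score) in (("sift", self.sift), ("polyphen", self.polyphen)):
            if score is not None and not 0.0 <= score <= 1.0:
                raise ValueError(f"{name} score {score} outside [0, 1]")

    @property
    def vid(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class ReferencePanel:
    """Alternate-allele frequencies per reference population.

    ``freqs`` maps ``variant id -> {population -> AF}``; a variant
    absent from a population has no entry (frequency unknown).
    ``european_populations`` names the subset used as the frequency-
    ratio denominator (e.g. the ESP European-American and the 1000
    Genomes European panels).
    """

    populations: list[str]
    freqs: dict[str, dict[str, float]]
    european_populations: tuple[str, ...] = ("ESP_EA", "KG_EUR")

    def variant_freqs(self, vid: str) -> dict[str, float]:
        return self.freqs.get(vid, {})


@dataclass
class EnrichmentResult:
    variant_id: str
    observed_af: float
    reference_af: float | None
    frequency_ratio: float  # may be math.inf when the panels lack the variant
    n_segregating_families: int
    passed: bool = False


# ------------------------------------------------------------- filters

def population_frequency_filter(variants, panel: ReferencePanel,
                                threshold: float = 0.02):
    """Keep variants whose AF is <= threshold in every reference
    population with a known frequency.

    A population without a frequency for the variant cannot fail it
    (vacuous pass); variants absent from every panel are retained and
    listed in the report.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    kept, report = [], {"removed": [], "absent_all_panels": []}
    for v in variants:
        fr = panel.variant_freqs(v.vid)
        if not fr:
            report["absent_all_panels"].append(v.vid)
        if all(af <= threshold for af in fr.values()):
            kept.append(v)
        else:
            report["removed"].append(v.vid)
    return kept, report


def impact_filter(variants):
    """Keep high-impact variants unconditionally; keep missense only
    with a SIFT 'deleterious' call and/or a PolyPhen2
    probably/possibly-damaging call.  Missense variants lacking both
    annotations are removed and counted."""
    kept, report = [], {"removed": [], "missense_unannotated": []}
    for v in variants:
        if v.consequence in HIGH_IMPACT:
            kept.append(v)
        elif v.consequence == "missense":
            sift_pred, _ = v.sift
            poly_pred, _ = v.polyphen
            if sift_pred is None and poly_pred is None:
                report["missense_unannotated"].append(v.vid)
                report["removed"].append(v.vid)
            elif sift_pred == "deleterious" or poly_pred in ("probably", "possibly"):
                kept.append(v)
            else:
                report["removed"].append(v.vid)
        else:
            report["removed"].append(v.vid)
    return kept, report


# ---------------------------------------------------------- enrichment

def observed_frequency(variant: VariantRecord,
                       probands: list[tuple[str, str]]) -> float:
    """Alternate-allele frequency among the per-family probands:
    alt allele count / (2 x probands with a non-missing call)."""
    alt = 0
    called = 0
    for key in probands:
        g = variant.genotypes.get(key)
        if g is None:
            continue
        called += 1
        alt += g
    if called == 0:
        raise ValueError(
            f"variant {variant.vid}: no proband has a genotype call")
    return alt / (2 * called)


def frequency_ratio(observed_af: float, panel: ReferencePanel, vid: str,
                    denominator: str = "max") -> tuple[float, float | None]:
    """Ratio of the proband allele frequency to the European reference
    frequency.

    ``denominator`` policy over the available European panels:
    ``max`` (conservative, default), ``min``, or a population label.
    Returns (ratio, reference_af); a variant absent from every European
    panel gets ratio +inf with reference None (flagged downstream).
    """
    if observed_af < 0:
        raise ValueError("observed_af must be non-negative")
    fr = panel.variant_freqs(vid)
    if denominator in ("max", "min"):
        eur = [fr[p] for p in panel.european_populations if p in fr]
        ref = (max(eur) if denominator == "max" else min(eur)) if eur else None
    else:
        ref = fr.get(denominator)
    if ref is None or ref == 0.0:
        return math.inf if observed_af > 0 else 0.0, ref
    return observed_af / ref, ref


def segregating_families(variant: VariantRecord, peds: list[Pedigree]) -> int:
    """Number of families with at least one sequenced affected carrier."""
    n = 0
    for ped in peds:
        for m in ped.wes_cases():
            g = variant.genotypes.get((ped.family_id, m.id))
            if g is not None and g > 0:
                n += 1
                break
    return n


def enrichment_stage(variants, panel: ReferencePanel, peds: list[Pedigree],
                     probands: list[tuple[str, str]], ratio_min: float = 2.0,
                     fam_min: int = 3, denominator: str = "max"):
    """Retain variants with frequency ratio >= ratio_min that segregate
    in >= fam_min families (both thresholds inclusive).

    Returns (retained EnrichmentResults, all EnrichmentResults).
    """
    results = []
    for v in variants:
        obs = observed_frequency(v, probands)
        ratio, ref = frequency_ratio(obs, panel, v.vid, denominator=denominator)
        nfam = segregating_families(v, peds)
        res = EnrichmentResult(v.vid, obs, ref, ratio, nfam,
                               passed=(ratio >= ratio_min and nfam >= fam_min))
        results.append(res)
    return [r for r in results if r.passed], results
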