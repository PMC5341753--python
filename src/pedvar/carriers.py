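"""Haplotype-based affected-carrier-frequency bounds.

The pipeline's core bespoke computation.  Within each family the
alternate allele observed in sequenced carriers is assigned to one or
two candidate founder haplotypes; every affected man on the family
roster — sequenced or not — whose haplotype pair contains a candidate
could carry the allele.  This yields per-family minimum and maximum
possible affected-carrier fractions, averaged across carrier families
into the min/max *average carrier frequency* used for candidate
selection.  The denominator is the full affected roster, which is what
lets families with a single sequenced case still contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .filtering import VariantRecord
from .pedigree import Pedigree

__all__ = [
    "HaplotypeMap",
    "CarrierBounds",
    "CarrierSummary",
    "candidate_haplotypes",
    "family_carrier_bounds",
    "average_carrier_frequency",
    "genotyped_carrier_counts",
]


@dataclass
class HaplotypeMap:
    """Founder-haplotype labels at one locus for one family.

    ``labels`` maps individual id -> ordered (paternal, maternal) pair
    of founder-haplotype labels; ``affected_roster`` lists all affected
    men in the family, with or without DNA.
    """

    family_id: str
    labels: dict[str, tuple[str, str]]
    affected_roster: list[str] = field(default_factory=list)

    def pair(self, iid: str) -> tuple[str, str] | None:
        return self.labels.get(iid)


@dataclass
class CarrierBounds:
    family_id: str
    candidate_haplotypes: frozenset[str]
    status: str  # {resolved, ambiguous, inconsistent}
    min_count: int
    max_count: int
    n_affected: int

    @property
    def min_frac(self) -> float:
        return self.min_count / self.n_affected

    @property
    def max_frac(self) -> float:
        return self.max_count / self.n_affected


@dataclass
class CarrierSummary:
    variant_id: str
    min_avg: float  # percent
    max_avg: float  # percent
    n_carrier_families: int
    n_affected_carriers: int | None = None
    n_unaffected_carriers: int | None = None


def candidate_haplotypes(ped: Pedigree, variant: VariantRecord,
                         hap_map: HaplotypeMap):
    """Candidate carrier haplotypes: the intersection of the sequenced
    carriers' label pairs.

    One shared label -> resolved; two (a single carrier, or carriers
    sharing both labels) -> ambiguous.  An empty intersection means the
    observed carriers cannot share a single founder haplotype
    (recombination or independent origin); we fall back to the union of
    their labels and flag the family inconsistent.  Homozygous carriers
    contribute both labels.
    """
    carrier_pairs = []
    for m in ped.wes_cases():
        g = variant.genotypes.get((ped.family_id, m.id))
        if g is None or g == 0:
            continue
        pair = hap_map.pair(m.id)
        if pair is None:
            raise ValueError(
                f"family {ped.family_id}: sequenced carrier {m.id} missing "
                "from the haplotype map")
        carrier_pairs.append(frozenset(pair))
    if not carrier_pairs:
        raise ValueError(
            f"family {ped.family_id}: no sequenced affected carrier for "
            f"{variant.vid}")
    cand = frozenset.intersection(*carrier_pairs)
    if not cand:
        union = frozenset.union(*carrier_pairs)
        warnings.warn(
            f"family {ped.family_id}, variant {variant.vid}: carrier "
            "haplotypes are inconsistent; using the union of carrier labels",
            stacklevel=2)
        return union, "inconsistent"
    return cand, ("resolved" if len(cand) == 1 else "ambiguous")


def family_carrier_bounds(ped: Pedigree, candidates: frozenset[str],
                          hap_map: HaplotypeMap, status: str = "ambiguous",
                          ) -> CarrierBounds:
    """Count, for each candidate haplotype, the affected men on the
    roster whose label pair contains it; the smallest and largest such
    counts bound the family's true affected-carrier count.

    Roster men absent from the haplotype map stay in the denominator
    but cannot be counted as potential carriers (warned).
    """
    if not candidates:
        raise ValueError("candidate haplotype set is empty")
    roster = hap_map.affected_roster or [m.id for m in ped.affected_men()]
    missing = [iid for iid in roster if hap_map.pair(iid) is None]
    if missing:
        warnings.warn(
            f"family {ped.family_id}: affected men {missing} lack haplotype "
            "data; kept in the denominator only", stacklevel=2)
    counts = []
    for h in sorted(candidates):
        counts.append(sum(1 for iid in roster
                          if (p := hap_map.pair(iid)) is not None and h in p))
    bounds = CarrierBounds(ped.family_id, candidates, status,
                           min_count=min(counts), max_count=max(counts),
                           n_affected=len(roster))
    if len(candidates) == 1:
        assert bounds.min_count == bounds.max_count
    return bounds


def average_carrier_frequency(variant_id: str,
                              bounds: list[CarrierBounds]) -> CarrierSummary:
    """Unweighted mean of the per-family min/max carrier fractions over
    carrier families, in percent."""
    if not bounds:
        raise ValueError(f"variant {variant_id}: no carrier family")
    min_avg = 100.0 * sum(b.min_frac for b in bounds) / len(bounds)
    max_avg = 100.0 * sum(b.max_frac for b in bounds) / len(bounds)
    return CarrierSummary(variant_id, min_avg, max_avg, len(bounds))


def genotyped_carrier_counts(variant: VariantRecord,
                             peds: list[Pedigree]) -> tuple[int, int]:
    """(affected, unaffected) carrier counts over genotyped family
    members, as reported after follow-up genotyping."""
    n_aff = n_unaff = 0
    for ped in peds:
        for m in ped.members.values():
            g = variant.genotypes.get((ped.family_id, m.id))
            if g is None or g == 0:
                continue
            if m.affected:
                n_aff += 1
            else:
                n_unaff += 1
    return n_aff, n_unaff
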