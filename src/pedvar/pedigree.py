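"""Pedigree data model, kinship, and family summary statistics.

Families here are multiplex hereditary prostate cancer (HPC) pedigrees:
several affected men per family, a subset of whom have whole-exome
sequence (WES) data.  The module provides the relatedness machinery the
prioritization pipeline needs — recursive kinship coefficients,
relationship degree, the size of the largest pairwise-distant set of
sequenced cases — plus binned family summaries.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "kinship_coefficient",
    "relationship_degree",
    "max_distant_wes_set",
    "select_wes_candidates",
    "family_summary",
    "read_pedigrees",
    "write_pedigrees",
]

UNRELATED = "unrelated"

# Far-degree sentinel used when ranking "most distantly related" sets:
# within a single family graph, an unrelated pair (e.g. two married-in
# lineages) is the most distant possible.
_UNRELATED_DEGREE = 99


@dataclass(frozen=True)
class Individual:
    """One pedigree member with the phenotype fields the pipeline uses.

    ``aggressive`` follows the study definition: Gleason score 8-10 or
    regional/distant stage (or death from the disease).  ``dx_age`` is
    the age at diagnosis in years, defined for affected men only.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "male"  # {male, female}
    affected: bool = False
    dx_age: float | None = None
    aggressive: bool | None = None
    vital: str = "alive"  # {alive, deceased}
    wes: bool = False
    dna_available: bool = True

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"invalid sex {self.sex!r} for {self.id}")
        if self.dx_age is not None and not self.affected:
            raise ValueError(f"dx_age set for unaffected individual {self.id}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """A single connected family graph.

    Invariants checked on construction: every parent id resolves to a
    member of the right sex, the graph is acyclic, has at least one
    founder, and is connected (parent-child edges plus mate edges).
    """

    def __init__(self, family_id: str, members: Iterable[Individual],
                 ancestry: str = "european"):
        self.family_id = family_id
        self.ancestry = ancestry
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise ValueError(f"duplicate individual id {ind.id!r}")
            self.members[ind.id] = ind
        if not self.members:
            raise ValueError(f"family {family_id}: no members")
        self._validate()
        self._depth: dict[str, int] = {}
        self._kin_cache: dict[tuple[str, str], float] = {}

    # -- validation -------------------------------------------------
    def _validate(self) -> None:
        for ind in self.members.values():
            for pid, want_sex in ((ind.father_id, "male"), (ind.mother_id, "female")):
                if pid is None:
                    continue
                parent = self.members.get(pid)
                if parent is None:
                    raise ValueError(
                        f"family {self.family_id}: parent {pid!r} of {ind.id!r} "
                        "is not a member")
                if parent.sex != want_sex:
                    raise ValueError(
                        f"family {self.family_id}: parent {pid!r} has sex "
                        f"{parent.sex}, expected {want_sex}")
        if not self.founders():
            raise ValueError(f"family {self.family_id}: no founder")
        self._check_acyclic()
        self._check_connected()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 visiting, 1 done

        def visit(iid: str) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                raise ValueError(
                    f"family {self.family_id}: {iid!r} is its own ancestor")
            state[iid] = 0
            ind = self.members[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    visit(pid)
            state[iid] = 1

        for iid in self.members:
            visit(iid)

    def _check_connected(self) -> None:
        adj: dict[str, set[str]] = {iid: set() for iid in self.members}
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    adj[ind.id].add(pid)
                    adj[pid].add(ind.id)
            # mate edge keeps childless couples connected
            if ind.father_id is not None and ind.mother_id is not None:
                adj[ind.father_id].add(ind.mother_id)
                adj[ind.mother_id].add(ind.father_id)
        seen: set[str] = set()
        stack = [next(iter(self.members))]
        while stack:
            iid = stack.pop()
            if iid in seen:
                continue
            seen.add(iid)
            stack.extend(adj[iid] - seen)
        if seen != set(self.members):
            raise ValueError(
                f"family {self.family_id}: pedigree is not a single connected graph")

    # -- accessors --------------------------------------------------
    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.is_founder]

    def affected_men(self) -> list[Individual]:
        return [m for m in self.members.values() if m.affected and m.sex == "male"]

    def wes_cases(self) -> list[Individual]:
        return [m for m in self.affected_men() if m.wes]

    def depth(self, iid: str) -> int:
        """Generation index: founders 0, child = 1 + max(parent depths)."""
        if iid in self._depth:
            return self._depth[iid]
        ind = self.members[iid]
        if ind.is_founder:
            d = 0
        else:
            d = 1 + max(self.depth(p) for p in (ind.father_id, ind.mother_id)
                        if p is not None)
        self._depth[iid] = d
        return d

    def with_member(self, ind: Individual) -> "Pedigree":
        new = dict(self.members)
        new[ind.id] = ind
        return Pedigree(self.family_id, new.values(), ancestry=self.ancestry)

    def update_member(self, iid: str, **changes) -> "Pedigree":
        return self.with_member(replace(self.members[iid], **changes))

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"Pedigree({self.family_id!r}, n={len(self)})"


# ---------------------------------------------------------------- kinship

def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b): probability that one allele drawn
    at random from each of a and b is identical by descent.

    Standard recursion: founders are mutually unrelated;
    phi(a, a) = 0.5 * (1 + phi(father, mother)); otherwise recurse on
    the individual deeper in the pedigree.
    """
    for iid in (a, b):
        if iid not in ped.members:
            raise KeyError(f"unknown individual id {iid!r} in family {ped.family_id}")
    return _kin(ped, a, b)


def _kin(ped: Pedigree, a: str, b: str) -> float:
    key = (a, b) if a <= b else (b, a)
    cached = ped._kin_cache.get(key)
    if cached is not None:
        return cached
    ia, ib = ped.members[a], ped.members[b]
    if a == b:
        if ia.is_founder:
            val = 0.5
        else:
            val = 0.5 * (1.0 + _parent_kin(ped, ia))
    else:
        # recurse on the deeper individual; ties broken arbitrarily
        if ped.depth(a) < ped.depth(b):
            ia, ib = ib, ia
            a, b = b, a
        if ia.is_founder:
            val = 0.0
        else:
            val = 0.5 * (
                (_kin(ped, ia.father_id, b) if ia.father_id else 0.0)
                + (_kin(ped, ia.mother_id, b) if ia.mother_id else 0.0))
    ped._kin_cache[key] = val
    return val


def _parent_kin(ped: Pedigree, ind: Individual) -> float:
    if ind.father_id is None or ind.mother_id is None:
        return 0.0
    return _kin(ped, ind.father_id, ind.mother_id)


def relationship_degree(ped: Pedigree, a: str, b: str) -> int | str:
    """Relationship degree from kinship: degree k satisfies
    phi = (1/2)^(k+1), so k = round(-log2(phi)) - 1; phi = 0 maps to
    ``"unrelated"``.  Non-dyadic kinship values (looped pedigrees) are
    classified by the same rounding rule.
    """
    if a == b:
        raise ValueError("relationship degree requires two distinct individuals")
    phi = kinship_coefficient(ped, a, b)
    if phi == 0.0:
        return UNRELATED
    import math

    return max(1, round(-math.log2(phi)) - 1)


def _pairwise_distant(ped: Pedigree, ids: tuple[str, ...], max_kinship: float) -> bool:
    return all(kinship_coefficient(ped, x, y) <= max_kinship
               for x, y in itertools.combinations(ids, 2))


def max_distant_wes_set(ped: Pedigree, max_kinship: float = 0.125) -> int:
    """Size of the largest set of WES'd affected men that is pairwise
    second-degree or more distant (kinship <= 1/8).

    Returns 0 when no such set of size >= 2 exists — including families
    with a single sequenced case.
    """
    ids = sorted(m.id for m in ped.wes_cases())
    for size in range(len(ids), 1, -1):
        for combo in itertools.combinations(ids, size):
            if _pairwise_distant(ped, combo, max_kinship):
                return size
    return 0


# ------------------------------------------------- WES case selection

def _phenotype_tier(ind: Individual) -> int:
    """Sequencing priority: aggressive disease first, then early onset
    (diagnosis at or before 65), then the rest."""
    if ind.aggressive:
        return 0
    if ind.dx_age is not None and ind.dx_age <= 65:
        return 1
    return 2


def select_wes_candidates(ped: Pedigree, k: int) -> list[str]:
    """Choose k affected men for sequencing.

    Priority: aggressive disease, then early-onset (dx_age <= 65), then
    sets maximizing the total pairwise relationship degree among the
    chosen ("most distantly related").  Exhaustive over subsets, with
    id-lexicographic tie-breaks, so the result is deterministic.
    """
    eligible = sorted((m for m in ped.affected_men() if m.dna_available),
                      key=lambda m: m.id)
    if k > len(eligible):
        raise ValueError(
            f"family {ped.family_id}: requested {k} WES candidates but only "
            f"{len(eligible)} affected men with DNA are available")
    if k == 0:
        return []

    def degree_value(x: str, y: str) -> int:
        d = relationship_degree(ped, x, y)
        return _UNRELATED_DEGREE if d == UNRELATED else d

    best_key = None
    best: tuple[Individual, ...] | None = None
    for combo in itertools.combinations(eligible, k):
        tiers = tuple(sorted(_phenotype_tier(m) for m in combo))
        dist = sum(degree_value(x.id, y.id)
                   for x, y in itertools.combinations(combo, 2))
        key = (tiers, -dist, tuple(m.id for m in combo))
        if best_key is None or key < best_key:
            best_key, best = key, combo
    assert best is not None
    return [m.id for m in sorted(best, key=lambda m: (_phenotype_tier(m), m.id))]


# --------------------------------------------------- family summaries

AFFECTED_BINS = [(3, 4), (5, 6), (7, 8), (9, 10), (11, 18)]
DX_AGE_BINS = [(50, 54.9), (55, 59.9), (60, 64.9), (65, 69.9), (70, 79.5)]
WES_BINS = [1, 2, 3, 4, 5, 6]
DISTANT_BINS = [0, 2, 3, 4]


def _bin_label(lo, hi) -> str:
    return f"{lo} - {hi}"


def family_summary(peds: list[Pedigree]) -> pd.DataFrame:
    """Binned counts of families by affected-man count, mean diagnosis
    age, number of sequenced cases, and largest pairwise-distant
    sequenced set, using the study's bin edges.

    Returns a tidy frame with columns (characteristic, bin, n_families).
    """
    if not peds:
        raise ValueError("family_summary requires at least one pedigree")
    rows = []

    def tally(name: str, values, bins, labeler):
        counts = {labeler(b): 0 for b in bins}
        for v in values:
            for b in bins:
                lo, hi = (b, b) if not isinstance(b, tuple) else b
                if lo <= v <= hi:
                    counts[labeler(b)] += 1
                    break
        for lab, n in counts.items():
            rows.append({"characteristic": name, "bin": lab, "n_families": n})

    n_affected = [len(p.affected_men()) for p in peds]
    mean_ages = []
    for p in peds:
        ages = [m.dx_age for m in p.affected_men() if m.dx_age is not None]
        mean_ages.append(sum(ages) / len(ages) if ages else float("nan"))
    n_wes = [len(p.wes_cases()) for p in peds]
    distant = [max_distant_wes_set(p) for p in peds]

    tally("n_affected", n_affected, AFFECTED_BINS, lambda b: _bin_label(*b))
    tally("mean_dx_age", mean_ages, DX_AGE_BINS, lambda b: _bin_label(*b))
    tally("n_wes", n_wes, WES_BINS, str)
    tally("max_distant_wes", distant, DISTANT_BINS, str)
    return pd.DataFrame(rows)


# ------------------------------------------------------------- PED I/O
# LINKAGE convention: sex 1=male 2=female, affection 2=affected
# 1=unaffected, 0=unknown; missing parent = "0".

def write_pedigrees(peds: list[Pedigree], ped_path: str | Path,
                    pheno_path: str | Path) -> None:
    """Write a 6-column PED file plus a phenotype TSV keyed by
    (family_id, individual_id)."""
    ped_rows, ph_rows = [], []
    for ped in peds:
        for m in ped.members.values():
            ped_rows.append([ped.family_id, m.id, m.father_id or "0",
                             m.mother_id or "0", 1 if m.sex == "male" else 2,
                             2 if m.affected else 1])
            ph_rows.append({
                "family_id": ped.family_id, "individual_id": m.id,
                "dx_age": "" if m.dx_age is None else m.dx_age,
                "aggressive": _tri(m.aggressive), "vital": m.vital,
                "wes": int(m.wes), "dna_available": int(m.dna_available),
                "ancestry": ped.ancestry,
            })
    pd.DataFrame(ped_rows).to_csv(ped_path, sep="\t", header=False, index=False)
    pd.DataFrame(ph_rows).to_csv(pheno_path, sep="\t", index=False)


def _tri(v: bool | None) -> str:
    return "" if v is None else str(int(v))


def read_pedigrees(ped_path: str | Path, pheno_path: str | Path) -> list[Pedigree]:
    ped = pd.read_csv(ped_path, sep="\t", header=None, dtype=str,
                      names=["family_id", "id", "father_id", "mother_id",
                             "sex", "affected"])
    ph = pd.read_csv(pheno_path, sep="\t", dtype=str).set_index(
        ["family_id", "individual_id"])
    out = []
    for fam, grp in ped.groupby("family_id", sort=True):
        members = []
        ancestry = "european"
        for _, r in grp.iterrows():
            p = ph.loc[(fam, r["id"])]
            ancestry = p.get("ancestry", "european") or "european"
            dx = p["dx_age"]
            agg = p["aggressive"]
            members.append(Individual(
                id=r["id"],
                father_id=None if r["father_id"] == "0" else r["father_id"],
                mother_id=None if r["mother_id"] == "0" else r["mother_id"],
                sex="male" if r["sex"] == "1" else "female",
                affected=r["affected"] == "2",
                dx_age=None if pd.isna(dx) or dx == "" else float(dx),
                aggressive=None if pd.isna(agg) or agg == "" else bool(int(float(agg))),
                vital=p["vital"],
                wes=bool(int(float(p["wes"]))),
                dna_available=bool(int(float(p["dna_available"]))),
            ))
        out.append(Pedigree(str(fam), members, ancestry=ancestry))
    return out
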