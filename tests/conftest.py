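import itertools

import numpy as np
import pytest

from pedvar.pedigree import Individual, Pedigree
from pedvar.simulate import SimulationSpec, simulate_study


def make_ped(family_id, rows, **ped_kwargs):
    """rows: (id, father, mother, sex, affected, dx_age, aggressive, wes)."""
    members = []
    for r in rows:
        iid, fa, mo, sex, aff = r[:5]
        dx = r[5] if len(r) > 5 else None
        agg = r[6] if len(r) > 6 else None
        wes = r[7] if len(r) > 7 else False
        members.append(Individual(
            id=iid, father_id=fa, mother_id=mo, sex=sex, affected=aff,
            dx_age=dx, aggressive=agg, wes=wes))
    return Pedigree(family_id, members, **ped_kwargs)


@pytest.fixture
def three_branch_ped():
    """Ten-member, three-generation family: grandparents, three married
    children, one grandson per branch.  s1, c2, c3 are pairwise
    avuncular/avuncular/cousins."""
    return make_ped("T1", [
        ("gf", None, None, "male", True, 70.0, False, False),
        ("gm", None, None, "female", False),
        ("s1", "gf", "gm", "male", True, 62.0, False, True),
        ("s1w", None, None, "female", False),
        ("s2", "gf", "gm", "male", True, 66.0, False, False),
        ("s2w", None, None, "female", False),
        ("d1", "gf", "gm", "female", False),
        ("d1h", None, None, "male", False),
        ("c1", "s1", "s1w", "male", True, 55.0, True, False),
        ("c2", "s2", "s2w", "male", True, 58.0, False, True),
        ("c3", "d1h", "d1", "male", True, 61.0, False, True),
    ])


def kinship_ibd_oracle(ped, a, b):
    """Exact kinship by enumerating every inheritance vector.

    Founders carry uniquely labelled alleles; each non-founder has four
    equally likely transmission choices.  The kinship coefficient is
    the probability that one allele drawn from each of a and b is
    identical by descent, averaged over all configurations.
    """
    ids = sorted(ped.members, key=lambda i: (ped.depth(i), i))
    nonfounders = [i for i in ids if not ped.members[i].is_founder]
    total = 0.0
    n_cfg = 0
    for cfg in itertools.product(range(4), repeat=len(nonfounders)):
        alleles = {}
        for i in ids:
            ind = ped.members[i]
            if ind.is_founder:
                alleles[i] = ((i, 0), (i, 1))
        for i, choice in zip(nonfounders, cfg):
            ind = ped.members[i]
            pat = alleles[ind.father_id][choice & 1]
            mat = alleles[ind.mother_id][(choice >> 1) & 1]
            alleles[i] = (pat, mat)
        hits = sum(alleles[a][x] == alleles[b][y]
                   for x in range(2) for y in range(2))
        total += hits / 4.0
        n_cfg += 1
    return total / n_cfg


@pytest.fixture(scope="session")
def study20():
    """A complete synthetic study reused across pipeline tests."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_study(SimulationSpec(n_families=20, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
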