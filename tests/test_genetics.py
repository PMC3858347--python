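"""Genetic rules: segregation, drive lethality, viability and costs."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from drivesim.genetics import (
    GeneticParams,
    GeneticSystem,
    Genotype,
    GenotypeTable,
    embryonic_cost_multiplier,
    fecundity_multiplier,
    gamete_distribution,
    kr_viable,
    medea_embryo_survives,
    offspring_survival_distribution,
)

M = GeneticSystem.MEDEA
KR = GeneticSystem.KR


def med(n):
    return Genotype(M, medea_copies=n)


def krg(k, r):
    return Genotype(KR, k_copies=k, r_copies=r)


# ---------------------------------------------------------------------------
# independent brute-force oracle: explicit ordered-allele Punnett squares
# ---------------------------------------------------------------------------


def _alleles(g):
    if g.system is M:
        return [["M"] * g.medea_copies + ["m"] * (2 - g.medea_copies)]
    return [
        ["K"] * g.k_copies + ["k"] * (2 - g.k_copies),
        ["R"] * g.r_copies + ["r"] * (2 - g.r_copies),
    ]


def punnett_oracle(mother, father, params):
    """Enumerate all ordered gamete pairs; apply survival rules per child."""
    out = {}
    m_loci, f_loci = _alleles(mother), _alleles(father)
    for m_pick in itertools.product(*[range(2) for _ in m_loci]):
        for f_pick in itertools.product(*[range(2) for _ in f_loci]):
            got = [
                (m_loci[i][m_pick[i]], f_loci[i][f_pick[i]])
                for i in range(len(m_loci))
            ]
            if mother.system is M:
                child = Genotype(M, medea_copies=sum(a == "M" for a in got[0]))
            else:
                child = Genotype(
                    KR,
                    k_copies=sum(a == "K" for a in got[0]),
                    r_copies=sum(a == "R" for a in got[1]),
                )
            w = 0.25 ** len(m_loci)
            out[child] = out.get(child, 0.0) + w
    result = {}
    for child, p in out.items():
        if mother.system is M:
            surv = 1.0
            if mother.medea_copies >= 1 and child.medea_copies == 0:
                surv *= 1.0 - params.medea_lethality
            surv *= (1.0 - params.c_M) ** child.medea_copies
        else:
            surv = 0.0 if (child.k_copies >= 1 and child.r_copies == 0) else 1.0
            surv *= (1.0 - params.c_K) ** child.k_copies
            surv *= (1.0 - params.c_R) ** child.r_copies
        result[child] = (p, surv)
    return result


# ---------------------------------------------------------------------------
# single-operation behaviour
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "parent, expected",
    [
        (med(1), {"M": 0.5, "m": 0.5}),
        (med(2), {"M": 1.0}),
        (med(0), {"m": 1.0}),
        (krg(1, 1), {"KR": 0.25, "Kr": 0.25, "kR": 0.25, "kr": 0.25}),
        (krg(2, 0), {"Kr": 1.0}),
    ],
)
def test_gamete_distribution_mendelian(parent, expected):
    dist = gamete_distribution(parent)
    assert dist == pytest.approx(expected)
    assert sum(dist.values()) == pytest.approx(1.0)


def test_medea_maternal_toxin_kills_noncarrier_embryos():
    p = GeneticParams(medea_lethality=1.0)
    assert medea_embryo_survives(med(1), med(0), p) == 0.0
    assert medea_embryo_survives(med(0), med(0), p) == 1.0
    assert medea_embryo_survives(med(2), med(1), p) == 1.0
    partial = GeneticParams(medea_lethality=0.8)
    assert medea_embryo_survives(med(1), med(0), partial) == pytest.approx(0.2)


def test_kr_viability_killer_unless_rescued():
    assert not kr_viable(krg(1, 0))
    assert not kr_viable(krg(2, 0))
    assert kr_viable(krg(0, 0))
    assert kr_viable(krg(2, 1))
    assert kr_viable(krg(1, 2))


@pytest.mark.parametrize(
    "genotype, params, expected",
    [
        (med(2), GeneticParams(c_M=0.1), 0.81),
        (med(1), GeneticParams(c_M=0.1), 0.9),
        (krg(1, 1), GeneticParams(c_K=0.1, c_R=0.1), 0.81),
        (krg(2, 2), GeneticParams(c_K=0.1, c_R=0.1), 0.81 * 0.81),
        (med(0), GeneticParams(c_M=0.5), 1.0),
    ],
)
def test_embryonic_cost_multiplicative_across_copies_and_loci(
    genotype, params, expected
):
    assert embryonic_cost_multiplier(genotype, params) == pytest.approx(expected)


def test_fecundity_cost_dominant_female_specific():
    p = GeneticParams(c_F=0.1)
    assert fecundity_multiplier(med(1), p) == pytest.approx(0.9)
    assert fecundity_multiplier(med(2), p) == pytest.approx(0.9)
    assert fecundity_multiplier(med(0), p) == 1.0
    # no fecundity cost in the KR system
    assert fecundity_multiplier(krg(2, 2), p) == 1.0


def test_cross_system_operations_raise():
    with pytest.raises(ValueError):
        medea_embryo_survives(krg(1, 1), krg(1, 1), GeneticParams())
    with pytest.raises(ValueError):
        kr_viable(med(1))
    with pytest.raises(ValueError):
        offspring_survival_distribution(med(1), krg(1, 1), GeneticParams())
    with pytest.raises(ValueError):
        Genotype(M, k_copies=1)
    with pytest.raises(ValueError):
        Genotype(M, medea_copies=3)


# ---------------------------------------------------------------------------
# composite distribution vs the brute-force oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "params",
    [
        GeneticParams(),
        GeneticParams(c_M=0.1, c_F=0.1, c_K=0.1, c_R=0.1),
        GeneticParams(c_M=0.3, c_K=0.25, c_R=0.05, medea_lethality=0.7),
    ],
)
def test_offspring_distribution_matches_punnett_oracle(params):
    medea_pairs = itertools.product([med(i) for i in range(3)], repeat=2)
    kr_pairs = itertools.product(
        [krg(k, r) for k in range(3) for r in range(3)], repeat=2
    )
    for mother, father in itertools.chain(medea_pairs, kr_pairs):
        got = offspring_survival_distribution(mother, father, params)
        want = punnett_oracle(mother, father, params)
        assert set(got) == set(want)
        for child in got:
            assert got[child][0] == pytest.approx(want[child][0], abs=1e-12)
            assert got[child][1] == pytest.approx(want[child][1], abs=1e-12)
        assert sum(p for p, _ in got.values()) == pytest.approx(1.0, abs=1e-12)


def test_worked_examples_of_brood_survival():
    p0 = GeneticParams(c_M=0.0, c_F=0.0)
    # Mm x Mm: mm quarter dies; survivors MM:Mm = 1:2, overall 3/4
    d = offspring_survival_distribution(med(1), med(1), p0)
    overall = sum(p * s for p, s in d.values())
    assert overall == pytest.approx(0.75)
    assert d[med(2)][0] / d[med(1)][0] == pytest.approx(0.5)
    # Mm mother x mm father: survivors all Mm, overall 1/2
    d = offspring_survival_distribution(med(1), med(0), p0)
    assert sum(p * s for p, s in d.values()) == pytest.approx(0.5)
    assert d[med(1)][1] == 1.0 and d[med(0)][1] == 0.0
    # KkRr x kkrr: only the Kk rr quarter dies
    d = offspring_survival_distribution(krg(1, 1), krg(0, 0), GeneticParams())
    assert sum(p * s for p, s in d.values()) == pytest.approx(0.75)
    assert d[krg(1, 0)][1] == 0.0


@given(
    c=st.floats(0, 1, allow_nan=False),
    lethality=st.floats(0, 1, allow_nan=False),
    mi=st.integers(0, 2),
    fi=st.integers(0, 2),
)
def test_medea_distribution_is_probabilistically_sound(c, lethality, mi, fi):
    params = GeneticParams(c_M=c, c_F=c, medea_lethality=lethality)
    d = offspring_survival_distribution(med(mi), med(fi), params)
    assert sum(p for p, _ in d.values()) == pytest.approx(1.0)
    assert all(0.0 <= s <= 1.0 and p >= 0.0 for p, s in d.values())


def test_neutral_limit_all_multipliers_one():
    p = GeneticParams(c_M=0, c_F=0, c_K=0, c_R=0, medea_lethality=0)
    for g in [med(i) for i in range(3)]:
        assert embryonic_cost_multiplier(g, p) == 1.0
        assert fecundity_multiplier(g, p) == 1.0
        assert medea_embryo_survives(med(1), g, p) == 1.0
    for k, r in itertools.product(range(3), repeat=2):
        assert embryonic_cost_multiplier(krg(k, r), p) == 1.0


def test_symmetry_in_parental_origin():
    # viability and costs depend on the offspring's own copy counts only
    params = GeneticParams(c_K=0.2, c_R=0.1)
    a = offspring_survival_distribution(krg(2, 0), krg(0, 2), params)
    b = offspring_survival_distribution(krg(0, 2), krg(2, 0), params)
    assert a == b


def test_genotype_table_consistent_with_dict_api():
    params = GeneticParams(c_M=0.1, c_F=0.1)
    table = GenotypeTable(M, params)
    for i, j in itertools.product(range(3), repeat=2):
        d = offspring_survival_distribution(med(i), med(j), params)
        for child, (p, s) in d.items():
            assert table.mendelian[i, j, child.index] == pytest.approx(p)
            assert table.hatch_survival[i, child.index] == pytest.approx(s)
    assert table.mendelian.sum(axis=2) == pytest.approx(np.ones((3, 3)))
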