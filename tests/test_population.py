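"""Spatial engine: development, emergence, mating, dispersal, oviposition."""

import numpy as np
import pytest

from drivesim.genetics import GeneticParams, GeneticSystem
from drivesim.population import (
    EGG,
    FEMALE,
    LARVA,
    MALE,
    PUPA,
    EnvironmentDay,
    GridState,
    LifecycleParams,
    develop_immatures,
    disperse_adults,
    emerge_adults,
    genotype_counts,
    mate_females,
    oviposit_females,
    step_day,
    temperature_factor,
)


def make_state(n_rows=3, n_cols=3, system=GeneticSystem.MEDEA, **lp_kwargs):
    lp = LifecycleParams(**lp_kwargs)
    state = GridState(n_rows, n_cols, system=system, lifecycle_params=lp,
                      genetic_params=GeneticParams())
    return state


# ---------------------------------------------------------------------------
# step_day basics
# ---------------------------------------------------------------------------


def test_empty_grid_is_fixed_point(rng):
    state = make_state()
    for day in range(5):
        log = step_day(state, EnvironmentDay(26.0, day), rng)
    assert state.n_adults == 0
    assert state.n_immatures == 0
    assert log.emerged == log.adult_deaths == log.eggs_laid == 0


def test_cohabiting_pair_mates_on_first_day(rng):
    state = make_state(adult_survival=1.0)
    state.add_container((1, 1))
    f = state.add_adults((1, 1), FEMALE, 0)[0]
    state.add_adults((1, 1), MALE, 2)
    step_day(state, EnvironmentDay(26.0, 0), rng)
    assert state.ad_mated[f]
    assert state.ad_mate_geno[f] == 2


def test_adult_conservation_across_steps(rng):
    state = make_state()
    for h in range(9):
        state.add_container(h)
    state.add_adults(np.repeat(np.arange(9), 4),
                     np.tile([FEMALE, MALE], 18), 1)
    for day in range(30):
        before = state.n_adults
        log = step_day(state, EnvironmentDay(26.0, day), rng)
        after = state.n_adults
        assert after == before + log.emerged - log.adult_deaths
        assert (state.co_count >= 0).all()


def test_agents_stay_in_grid(rng):
    state = make_state(2, 5)
    state.add_adults(np.zeros(40, dtype=int), np.tile([0, 1], 20), 0)
    for day in range(25):
        step_day(state, EnvironmentDay(26.0, day), rng)
        assert ((state.ad_house >= 0) & (state.ad_house < 10)).all()


def test_monogamy_mate_genotype_written_once(rng):
    state = make_state(1, 1, adult_survival=1.0)
    state.add_container(0)
    fidx = state.add_adults(0, FEMALE, 0, n=20)
    state.add_adults(0, MALE, 2, n=5)
    step_day(state, EnvironmentDay(26.0, 0), rng)
    first = state.ad_mate_geno[fidx].copy()
    assert (first == 2).all()
    # introduce wild-type males: stored mates must not change
    state.add_adults(0, MALE, 0, n=50)
    for day in range(10):
        step_day(state, EnvironmentDay(26.0, day), rng)
    np.testing.assert_array_equal(state.ad_mate_geno[fidx], first)


# ---------------------------------------------------------------------------
# development and emergence
# ---------------------------------------------------------------------------


def test_temperature_factor_band():
    lp = LifecycleParams()
    assert temperature_factor(26.0, lp) == 1.0
    assert temperature_factor(20.0, lp) == pytest.approx(0.5)
    assert temperature_factor(10.0, lp) == 0.0
    assert temperature_factor(45.0, lp) == 0.0
    assert temperature_factor(30.0, lp) == 1.0


def test_egg_stage_duration_at_reference_temperature(rng):
    state = make_state(1, 1, egg_survival=1.0)
    c = state.add_container(0)
    state.add_cohort(c, EGG, MALE, 0, 100, hatch_survival=1.0)
    days_to_hatch = 0
    while state.co_stage[0] == EGG:
        develop_immatures(state, 26.0, rng)
        days_to_hatch += 1
    assert days_to_hatch == state.params.d_egg
    assert state.co_stage[0] == LARVA


def test_starvation_halts_growth_and_reduces_survival(rng):
    lp = dict(larva_survival=1.0, starvation_factor=0.5)
    fed = make_state(1, 1, **lp)
    cf = fed.add_container(0, rate=100.0, food=1000.0)
    fed.add_cohort(cf, LARVA, MALE, 0, 1000, mass=0.1)
    starved = make_state(1, 1, **lp)
    cs = starved.add_container(0, rate=0.0, food=0.0)
    starved.add_cohort(cs, LARVA, MALE, 0, 1000, mass=0.1)
    develop_immatures(fed, 26.0, rng)
    develop_immatures(starved, 26.0, rng)
    assert starved.co_mass[0] == pytest.approx(0.1)  # no growth
    assert fed.co_mass[0] > 0.1
    assert fed.co_count[0] == 1000
    # starved survival = starvation_factor x nominal
    assert starved.co_count[0] < 1000
    assert starved.co_count[0] == pytest.approx(500, abs=60)


def test_shared_container_lowers_per_capita_growth(rng):
    shared = make_state(1, 1)
    c = shared.add_container(0, rate=2.0, food=10.0)
    shared.add_cohort(c, LARVA, MALE, 0, 100, mass=0.1)
    shared.add_cohort(c, LARVA, FEMALE, 0, 100, mass=0.1)
    alone = make_state(1, 1)
    c1 = alone.add_container(0, rate=2.0, food=10.0)
    alone.add_cohort(c1, LARVA, MALE, 0, 100, mass=0.1)
    develop_immatures(shared, 26.0, rng)
    develop_immatures(alone, 26.0, rng)
    assert shared.co_mass[0] < alone.co_mass[0]


def test_emergence_bookkeeping(rng):
    state = make_state(1, 2, pupa_survival=1.0)
    c = state.add_container(0)
    state.add_cohort(c, PUPA, MALE, 1, 5, dev=0.9, mass=1.2)
    emerged = develop_immatures(state, 26.0, rng)
    n = emerge_adults(state, emerged)
    assert n == 5
    assert state.n_adults == 5
    assert (state.ad_sex == MALE).all()
    assert (state.ad_geno == 1).all()
    np.testing.assert_allclose(state.ad_size, 1.2)
    assert len(state.co_count) == 0  # cohort removed


def test_wellfed_cohorts_emerge_larger(rng):
    def rear(food_rate):
        state = make_state(1, 1, larva_survival=1.0, egg_survival=1.0,
                           pupa_survival=1.0)
        c = state.add_container(0, rate=food_rate, food=food_rate * 5)
        state.add_cohort(c, LARVA, MALE, 0, 50, mass=0.1)
        sizes = []
        for _ in range(30):
            emerged = develop_immatures(state, 26.0, rng)
            if len(emerged["count"]) and emerged["count"].sum():
                sizes.extend(np.repeat(emerged["mass"], emerged["count"]))
            if not len(state.co_count):
                break
        return np.mean(sizes)

    assert rear(50.0) > rear(0.5)


# ---------------------------------------------------------------------------
# mating
# ---------------------------------------------------------------------------


def test_mate_choice_proportional_to_size(rng):
    state = make_state(1, 1, system=GeneticSystem.MEDEA)
    state.add_container(0)
    # three males distinguishable by genotype, sizes 2, 1, 1
    for geno, size in ((0, 2.0), (1, 1.0), (2, 1.0)):
        state.add_adults(0, MALE, geno, size)
    fidx = state.add_adults(0, FEMALE, 0, n=20000)
    mate_females(state, rng)
    chosen = state.ad_mate_geno[fidx]
    freqs = np.bincount(chosen, minlength=3) / len(fidx)
    assert freqs[0] == pytest.approx(0.5, abs=0.015)
    assert freqs[1] == pytest.approx(0.25, abs=0.015)
    assert freqs[2] == pytest.approx(0.25, abs=0.015)


def test_no_males_no_mating(rng):
    state = make_state()
    fidx = state.add_adults((0, 0), FEMALE, 0, n=5)
    # a male in a different house does not count
    state.add_adults((2, 2), MALE, 0)
    mate_females(state, rng, house=(0, 0))
    assert not state.ad_mated[fidx].any()


# ---------------------------------------------------------------------------
# dispersal
# ---------------------------------------------------------------------------


def test_interior_dispersal_binomial_and_uniform_directions(rng):
    state = make_state(3, 3)
    n = 100_000
    start = 1 * 3 + 1  # centre house
    state.add_adults(np.full(n, start), np.zeros(n, dtype=int), 0)
    moved = disperse_adults(state, rng)
    frac = moved / n
    se = np.sqrt(0.3 * 0.7 / n)
    assert abs(frac - 0.30) < 3 * se
    dest = state.ad_house[state.ad_house != start]
    counts = np.bincount(dest, minlength=9)
    for h in (1, 3, 5, 7):
        assert counts[h] / n == pytest.approx(0.075, abs=0.005)


def test_zero_dispersal_probability_never_moves(rng):
    state = make_state(3, 3, p_disperse=0.0)
    idx = state.add_adults(np.full(1000, 4), np.zeros(1000, dtype=int), 0)
    disperse_adults(state, rng)
    assert (state.ad_house[idx] == 4).all()


def test_corner_house_blocked_draws_stay(rng):
    # two of four directions point off-grid: move frequency 0.15
    state = make_state(3, 3)
    n = 100_000
    state.add_adults(np.zeros(n, dtype=int), np.zeros(n, dtype=int), 0)
    moved = disperse_adults(state, rng)
    assert moved / n == pytest.approx(0.15, abs=0.01)


def test_corner_house_redraw_rule_moves_at_full_rate(rng):
    state = make_state(3, 3, edge_rule="redraw")
    n = 50_000
    state.add_adults(np.zeros(n, dtype=int), np.zeros(n, dtype=int), 0)
    moved = disperse_adults(state, rng)
    assert moved / n == pytest.approx(0.30, abs=0.02)
    assert set(np.unique(state.ad_house)) <= {0, 1, 3}


# ---------------------------------------------------------------------------
# oviposition
# ---------------------------------------------------------------------------


def _mated_females(state, house, geno, mate_geno, n):
    idx = state.add_adults(house, FEMALE, geno, n=n)
    state.ad_mated[idx] = True
    state.ad_mate_geno[idx] = mate_geno
    return idx


def test_wildtype_batch_mean(rng):
    state = make_state(1, 1)
    state.add_container(0)
    _mated_females(state, 0, 0, 0, 2000)
    total = oviposit_females(state, rng, always=True)
    mean = total / 2000
    assert mean == pytest.approx(60.0, abs=1.0)
    assert (state.co_geno == 0).all()
    assert (state.co_hs == 1.0).all()


def test_medea_carrier_batch_reduced_and_half_brood_doomed(rng):
    # Mm mother (c_F=0.1) x mm father: mean egg output 54; the mm half of
    # the brood carries hatch survival 0 under complete lethality
    state = make_state(1, 1)
    state.add_container(0)
    _mated_females(state, 0, 1, 0, 2000)
    total = oviposit_females(state, rng, always=True)
    assert total / 2000 == pytest.approx(54.0, abs=1.0)
    counts = np.bincount(state.co_geno, weights=state.co_count, minlength=3)
    assert counts[0] == pytest.approx(counts[1], rel=0.05)
    doomed = state.co_count[state.co_hs == 0.0].sum()
    assert doomed / total == pytest.approx(0.5, abs=0.02)


def test_unmated_or_containerless_females_lay_nothing(rng):
    state = make_state(1, 2)
    state.add_container(0)
    state.add_adults(0, FEMALE, 0, n=10)  # unmated
    assert oviposit_females(state, rng, always=True) == 0
    state2 = make_state(1, 1)  # no containers at all
    _mated_females(state2, 0, 0, 0, 10)
    assert oviposit_females(state2, rng, always=True) == 0


def test_eggs_only_laid_in_accepting_containers(rng):
    state = make_state(1, 1)
    release = state.add_container(0, accepts_oviposition=False,
                                  is_release=True, food=100.0)
    natural = state.add_container(0)
    _mated_females(state, 0, 0, 0, 100)
    oviposit_females(state, rng, always=True)
    assert (state.co_cont == natural).all()
    assert release not in state.co_cont


def test_seed_determinism_identical_runs():
    def run(seed):
        rng = np.random.default_rng(seed)
        state = make_state()
        for h in range(9):
            state.add_container(h)
        state.add_adults(np.repeat(np.arange(9), 6),
                         np.tile([FEMALE, MALE], 27), 0)
        for day in range(40):
            step_day(state, EnvironmentDay(26.0, day), rng)
        return genotype_counts(state), state.ad_house[state.ad_alive]

    c1, h1 = run(7)
    c2, h2 = run(7)
    np.testing.assert_array_equal(c1, c2)
    np.testing.assert_array_equal(h1, h2)
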