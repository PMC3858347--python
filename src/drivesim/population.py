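"""Stochastic spatial population engine.

The model world is a rectangular grid of houses.  Each house holds
water-filled containers in which immature mosquitoes develop as
age-synchronised cohorts (eggs, larvae, pupae), and individually tracked
adults.  One call to :func:`step_day` advances the world by one day,
applying in fixed order:

1. immature development and survival in every container (temperature sets
   the development rate; larvae compete for a shared per-container food
   pool that is replenished daily);
2. emergence of mature pupae into adults, whose body size is the
   per-capita larval mass attained;
3. scheduled releases for the day (delegated to :mod:`drivesim.release`);
4. adult survival (constant daily probability);
5. mating within houses — females are strictly monogamous and mate on the
   first day they share a house with at least one male, choosing a mate
   with probability proportional to his size;
6. nearest-neighbour dispersal: each adult moves with probability
   ``p_disperse`` (default 0.30) to an orthogonally adjacent house, the
   direction drawn uniformly; a draw pointing off the grid means no
   movement that day (a redraw-among-valid-directions variant is available
   via ``edge_rule='redraw'``);
7. oviposition by mated females into a randomly chosen accepting container
   of their current house, with mean batch size scaled by the mother's
   fecundity multiplier and offspring genotypes drawn from the Mendelian
   distribution of the stored mating pair.  Gene-drive lethality and
   embryonic fitness costs are applied when an egg cohort hatches.

State is stored in flat numpy arrays (one row per container, cohort or
adult) so that every daily operation is vectorised; all stochastic draws
consume a single :class:`numpy.random.Generator` passed by the caller,
which makes replicates exactly reproducible from a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import GeneticParams, GeneticSystem, GenotypeTable

__all__ = [
    "EGG",
    "LARVA",
    "PUPA",
    "FEMALE",
    "MALE",
    "LifecycleParams",
    "EnvironmentDay",
    "GridState",
    "DayLog",
    "temperature_factor",
    "step_day",
    "develop_immatures",
    "emerge_adults",
    "mate_females",
    "disperse_adults",
    "disperse_adult",
    "oviposit_females",
    "seed_population",
    "genotype_counts",
    "adult_counts_frame",
]

EGG, LARVA, PUPA = 0, 1, 2
FEMALE, MALE = 0, 1

_DR = np.array([-1, 1, 0, 0])  # N, S, W, E
_DC = np.array([0, 0, -1, 1])


@dataclass(frozen=True)
class LifecycleParams:
    """Demographic and environmental response parameters.

    Stage durations are days at the reference (optimal) temperature; the
    development rate scales linearly from zero at ``t_min`` up to 1 at
    ``t_opt`` and stays at 1 up to ``t_max``, outside of which no
    development occurs.  Larval food intake follows a shared-pool ration
    rule: each larva demands ``larval_demand`` mass units per day (times
    the temperature factor); when a container cannot meet total demand all
    its larvae receive the same fractional ration, which proportionally
    reduces growth and scales daily survival down to
    ``starvation_factor`` x the nominal rate at zero ration.
    """

    d_egg: float = 3.0
    d_larva: float = 8.0
    d_pupa: float = 2.0
    t_min: float = 14.0
    t_opt: float = 26.0
    t_max: float = 40.0
    egg_survival: float = 0.99
    larva_survival: float = 0.99
    pupa_survival: float = 0.99
    adult_survival: float = 0.89
    starvation_factor: float = 0.5
    larval_demand: float = 0.12
    growth_efficiency: float = 1.0
    egg_mass: float = 0.1
    base_batch: float = 60.0
    p_oviposit: float = 1.0 / 3.0
    p_disperse: float = 0.30
    edge_rule: str = "stay"  # "stay" | "redraw"
    food_cap_days: float = 5.0
    adult_size_mean: float = 1.0


@dataclass(frozen=True)
class EnvironmentDay:
    """Environmental forcing for one simulated day."""

    temperature: float
    day_index: int = 0


def temperature_factor(temperature: float, params: LifecycleParams) -> float:
    """Development-rate multiplier in [0, 1] for a daily mean temperature."""
    t = temperature
    if t <= params.t_min or t >= params.t_max:
        return 0.0
    if t >= params.t_opt:
        return 1.0
    return (t - params.t_min) / (params.t_opt - params.t_min)


@dataclass
class DayLog:
    """Bookkeeping of one day's events (used by tests and run logging)."""

    emerged: int = 0
    released_adults: int = 0
    released_eggs: int = 0
    adult_deaths: int = 0
    eggs_laid: int = 0
    matings: int = 0


class GridState:
    """Array-backed state of the house grid.

    Containers, immature cohorts and adults are stored as parallel flat
    arrays.  Houses are indexed row-major: ``house = row * n_cols + col``.
    """

    def __init__(
        self,
        n_rows: int,
        n_cols: int,
        *,
        system: GeneticSystem = GeneticSystem.WILDTYPE,
        genetic_params: GeneticParams | None = None,
        lifecycle_params: LifecycleParams | None = None,
    ) -> None:
        if n_rows < 1 or n_cols < 1:
            raise ValueError("grid must have positive dimensions")
        self.n_rows = n_rows
        self.n_cols = n_cols
        self.genetic_params = genetic_params or GeneticParams()
        self.params = lifecycle_params or LifecycleParams()
        self.table = GenotypeTable(system, self.genetic_params)

        # containers
        self.cont_house = np.empty(0, dtype=np.int64)
        self.cont_food = np.empty(0, dtype=float)
        self.cont_rate = np.empty(0, dtype=float)
        self.cont_accepts = np.empty(0, dtype=bool)
        self.cont_release = np.empty(0, dtype=bool)
        self.cont_active = np.empty(0, dtype=bool)

        # immature cohorts
        self.co_cont = np.empty(0, dtype=np.int64)
        self.co_stage = np.empty(0, dtype=np.int8)
        self.co_sex = np.empty(0, dtype=np.int8)
        self.co_geno = np.empty(0, dtype=np.int16)
        self.co_count = np.empty(0, dtype=np.int64)
        self.co_dev = np.empty(0, dtype=float)
        self.co_mass = np.empty(0, dtype=float)
        self.co_hs = np.empty(0, dtype=float)

        # adults
        self.ad_house = np.empty(0, dtype=np.int64)
        self.ad_sex = np.empty(0, dtype=np.int8)
        self.ad_geno = np.empty(0, dtype=np.int16)
        self.ad_size = np.empty(0, dtype=float)
        self.ad_age = np.empty(0, dtype=np.int32)
        self.ad_mated = np.empty(0, dtype=bool)
        self.ad_mate_geno = np.empty(0, dtype=np.int16)
        self.ad_alive = np.empty(0, dtype=bool)

        self._acc_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- properties -------------------------------------------------------
    @property
    def system(self) -> GeneticSystem:
        return self.table.system

    @property
    def n_houses(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def n_containers(self) -> int:
        return len(self.cont_house)

    @property
    def n_adults(self) -> int:
        return int(self.ad_alive.sum())

    @property
    def n_immatures(self) -> int:
        return int(self.co_count.sum())

    # -- construction -----------------------------------------------------
    def add_container(
        self,
        house: int | tuple[int, int],
        rate: float = 2.0,
        *,
        accepts_oviposition: bool = True,
        is_release: bool = False,
        food: float | None = None,
    ) -> int:
        """Append a container; returns its index."""
        h = self._house_index(house)
        if is_release and accepts_oviposition:
            raise ValueError("release containers never accept oviposition")
        if food is None:
            food = self.params.food_cap_days * rate
        self.cont_house = np.append(self.cont_house, h)
        self.cont_food = np.append(self.cont_food, float(food))
        self.cont_rate = np.append(self.cont_rate, float(rate))
        self.cont_accepts = np.append(self.cont_accepts, accepts_oviposition)
        self.cont_release = np.append(self.cont_release, is_release)
        self.cont_active = np.append(self.cont_active, True)
        self._acc_cache = None
        return self.n_containers - 1

    def add_cohort(
        self,
        container: int,
        stage: int,
        sex: int,
        genotype: int,
        count: int,
        *,
        dev: float = 0.0,
        mass: float | None = None,
        hatch_survival: float = 1.0,
    ) -> None:
        if count < 0:
            raise ValueError("cohort count must be non-negative")
        if mass is None:
            mass = self.params.egg_mass
        self.co_cont = np.append(self.co_cont, container)
        self.co_stage = np.append(self.co_stage, np.int8(stage))
        self.co_sex = np.append(self.co_sex, np.int8(sex))
        self.co_geno = np.append(self.co_geno, np.int16(genotype))
        self.co_count = np.append(self.co_count, count)
        self.co_dev = np.append(self.co_dev, dev)
        self.co_mass = np.append(self.co_mass, mass)
        self.co_hs = np.append(self.co_hs, hatch_survival)

    def add_adults(
        self,
        house: np.ndarray | int | tuple[int, int],
        sex: np.ndarray | int,
        genotype: np.ndarray | int,
        size: np.ndarray | float | None = None,
        *,
        age: int = 0,
        n: int | None = None,
    ) -> np.ndarray:
        """Append living, unmated adults; returns their row indices."""
        if isinstance(house, tuple):
            house = self._house_index(house)
        house = np.atleast_1d(np.asarray(house, dtype=np.int64))
        sex = np.broadcast_to(np.asarray(sex, dtype=np.int8), house.shape)
        genotype = np.broadcast_to(np.asarray(genotype, dtype=np.int16), house.shape)
        if size is None:
            size = self.params.adult_size_mean
        size = np.broadcast_to(np.asarray(size, dtype=float), house.shape)
        if n is not None and len(house) == 1:
            house = np.repeat(house, n)
            sex = np.repeat(sex, n)
            genotype = np.repeat(genotype, n)
            size = np.repeat(size, n)
        m = len(house)
        start = len(self.ad_house)
        self.ad_house = np.concatenate([self.ad_house, house])
        self.ad_sex = np.concatenate([self.ad_sex, sex])
        self.ad_geno = np.concatenate([self.ad_geno, genotype])
        self.ad_size = np.concatenate([self.ad_size, size])
        self.ad_age = np.concatenate([self.ad_age, np.full(m, age, dtype=np.int32)])
        self.ad_mated = np.concatenate([self.ad_mated, np.zeros(m, dtype=bool)])
        self.ad_mate_geno = np.concatenate(
            [self.ad_mate_geno, np.full(m, -1, dtype=np.int16)]
        )
        self.ad_alive = np.concatenate([self.ad_alive, np.ones(m, dtype=bool)])
        return np.arange(start, start + m)

    # -- helpers ----------------------------------------------------------
    def _house_index(self, house: int | tuple[int, int]) -> int:
        if isinstance(house, tuple):
            r, c = house
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"house {house} outside grid")
            return r * self.n_cols + c
        return int(house)

    def adults_in_house(self, house: int | tuple[int, int]) -> np.ndarray:
        h = self._house_index(house)
        return np.flatnonzero(self.ad_alive & (self.ad_house == h))

    def accepting_containers(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted container ids, per-house offsets) of accepting containers."""
        if self._acc_cache is None:
            ids = np.flatnonzero(
                self.cont_accepts & self.cont_active & ~self.cont_release
            )
            order = np.argsort(self.cont_house[ids], kind="stable")
            ids = ids[order]
            offsets = np.searchsorted(
                self.cont_house[ids], np.arange(self.n_houses + 1)
            )
            self._acc_cache = (ids, offsets)
        return self._acc_cache

    def compact_adults(self) -> None:
        """Drop dead adult rows (bookkeeping only; no model effect)."""
        keep = self.ad_alive
        for name in (
            "ad_house",
            "ad_sex",
            "ad_geno",
            "ad_size",
            "ad_age",
            "ad_mated",
            "ad_mate_geno",
            "ad_alive",
        ):
            setattr(self, name, getattr(self, name)[keep])

    def _maybe_compact(self) -> None:
        n = len(self.ad_alive)
        if n > 2048 and self.ad_alive.sum() < n // 2:
            self.compact_adults()


# ---------------------------------------------------------------------------
# Daily operations
# ---------------------------------------------------------------------------


def develop_immatures(
    state: GridState, temperature: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Advance every immature cohort by one day.

    Returns the mature pupal rows ready to emerge, as a dict of arrays
    (``cont``, ``sex``, ``geno``, ``count``, ``mass``).
    """
    p = state.params
    phi = temperature_factor(temperature, p)
    emerged = {
        "cont": np.empty(0, dtype=np.int64),
        "sex": np.empty(0, dtype=np.int8),
        "geno": np.empty(0, dtype=np.int16),
        "count": np.empty(0, dtype=np.int64),
        "mass": np.empty(0, dtype=float),
    }
    ncont = state.n_containers
    if len(state.co_count):
        stage0 = state.co_stage.copy()
        is_egg = stage0 == EGG
        is_larva = stage0 == LARVA
        is_pupa = stage0 == PUPA

        # shared-food-pool larval ration
        demand_pc = p.larval_demand * phi
        larv_counts = np.bincount(
            state.co_cont[is_larva],
            weights=state.co_count[is_larva].astype(float),
            minlength=ncont,
        )
        total_demand = larv_counts * demand_pc
        ration_frac = np.ones(ncont)
        hungry = total_demand > 0
        ration_frac[hungry] = np.minimum(
            1.0, state.cont_food[hungry] / total_demand[hungry]
        )
        state.cont_food -= np.minimum(state.cont_food, total_demand)
        rf = ration_frac[state.co_cont]

        # growth (larvae only)
        state.co_mass[is_larva] += (
            demand_pc * p.growth_efficiency * rf[is_larva]
        )

        # survival
        psurv = np.empty(len(stage0))
        psurv[is_egg] = p.egg_survival
        psurv[is_pupa] = p.pupa_survival
        psurv[is_larva] = p.larva_survival * (
            p.starvation_factor + (1.0 - p.starvation_factor) * rf[is_larva]
        )
        state.co_count = rng.binomial(state.co_count, psurv)

        # development progress
        dur = np.empty(len(stage0))
        dur[is_egg] = p.d_egg
        dur[is_larva] = p.d_larva
        dur[is_pupa] = p.d_pupa
        state.co_dev += phi / dur

        adv = (state.co_dev >= 1.0) & (state.co_count > 0)
        hatch = adv & is_egg
        if hatch.any():
            # drive lethality and embryonic costs act at hatch
            state.co_count[hatch] = rng.binomial(
                state.co_count[hatch], state.co_hs[hatch]
            )
            state.co_stage[hatch] = LARVA
            state.co_dev[hatch] = 0.0
            state.co_mass[hatch] = p.egg_mass
        pupate = adv & is_larva
        if pupate.any():
            state.co_stage[pupate] = PUPA
            state.co_dev[pupate] = 0.0
        mature = adv & is_pupa & (state.co_count > 0)
        if mature.any():
            emerged = {
                "cont": state.co_cont[mature].copy(),
                "sex": state.co_sex[mature].copy(),
                "geno": state.co_geno[mature].copy(),
                "count": state.co_count[mature].copy(),
                "mass": state.co_mass[mature].copy(),
            }
        keep = (state.co_count > 0) & ~mature
        for name in (
            "co_cont",
            "co_stage",
            "co_sex",
            "co_geno",
            "co_count",
            "co_dev",
            "co_mass",
            "co_hs",
        ):
            setattr(state, name, getattr(state, name)[keep])

    # replenish natural containers (constant daily rate, capped)
    nat = state.cont_active & ~state.cont_release
    state.cont_food[nat] = np.minimum(
        state.cont_food[nat] + state.cont_rate[nat],
        p.food_cap_days * state.cont_rate[nat],
    )
    # a release container is removed once all its occupants died or emerged
    if state.cont_release.any():
        occupied = np.zeros(ncont, dtype=bool)
        if len(state.co_cont):
            occupied[np.unique(state.co_cont)] = True
        retire = state.cont_active & state.cont_release & ~occupied
        state.cont_active[retire] = False
    return emerged


def emerge_adults(
    state: GridState, emerged: dict[str, np.ndarray]
) -> int:
    """Turn mature pupal cohorts into adults; returns the number emerged."""
    counts = emerged["count"]
    if len(counts) == 0 or counts.sum() == 0:
        return 0
    houses = np.repeat(state.cont_house[emerged["cont"]], counts)
    sexes = np.repeat(emerged["sex"], counts)
    genos = np.repeat(emerged["geno"], counts)
    sizes = np.repeat(emerged["mass"], counts)
    state.add_adults(houses, sexes, genos, sizes)
    return int(counts.sum())


def survive_adults(state: GridState, rng: np.random.Generator) -> int:
    """Daily adult survival draw; returns the number of deaths."""
    alive = np.flatnonzero(state.ad_alive)
    if len(alive) == 0:
        return 0
    die = rng.random(len(alive)) >= state.params.adult_survival
    state.ad_alive[alive[die]] = False
    state.ad_age[alive[~die]] += 1
    state._maybe_compact()
    return int(die.sum())


def mate_females(
    state: GridState,
    rng: np.random.Generator,
    house: int | tuple[int, int] | None = None,
) -> int:
    """Mate every unmated female that shares a house with >= 1 male.

    Mates are drawn with probability proportional to male body size; a
    female's mate genotype is stored once and never overwritten (strict
    monogamy).  Restricting to a single ``house`` is supported for
    fine-grained use.  Returns the number of new matings.
    """
    fem = state.ad_alive & (state.ad_sex == FEMALE) & ~state.ad_mated
    mal = state.ad_alive & (state.ad_sex == MALE)
    if house is not None:
        h = state._house_index(house)
        fem &= state.ad_house == h
        mal &= state.ad_house == h
    if not fem.any() or not mal.any():
        return 0
    fidx = np.flatnonzero(fem)
    midx = np.flatnonzero(mal)
    mh = state.ad_house[midx]
    order = np.argsort(mh, kind="stable")
    midx = midx[order]
    mh = mh[order]
    bounds = np.searchsorted(mh, np.arange(state.n_houses + 1))
    weights = state.ad_size[midx]
    cw = np.cumsum(weights)
    fh = state.ad_house[fidx]
    start, end = bounds[fh], bounds[fh + 1]
    has_male = end > start
    fidx, fh, start, end = fidx[has_male], fh[has_male], start[has_male], end[has_male]
    if len(fidx) == 0:
        return 0
    base = np.where(start > 0, cw[start - 1], 0.0)
    total = cw[end - 1] - base
    target = base + rng.random(len(fidx)) * total
    pick = np.searchsorted(cw, target, side="right")
    pick = np.clip(pick, start, end - 1)
    state.ad_mate_geno[fidx] = state.ad_geno[midx[pick]]
    state.ad_mated[fidx] = True
    return len(fidx)


def disperse_adults(
    state: GridState,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
) -> int:
    """One day of nearest-neighbour dispersal; returns the number moved.

    With probability ``p_disperse`` an adult draws one of the four compass
    directions uniformly; under the default ``'stay'`` edge rule a draw
    pointing off-grid results in no movement, while ``'redraw'`` draws
    uniformly among the existing neighbours instead.
    """
    p = state.params
    idx = np.flatnonzero(state.ad_alive) if indices is None else np.asarray(indices)
    n = len(idx)
    if n == 0:
        return 0
    move = rng.random(n) < p.p_disperse
    r = state.ad_house[idx] // state.n_cols
    c = state.ad_house[idx] % state.n_cols
    if p.edge_rule == "redraw":
        valid = np.stack(
            [r > 0, r < state.n_rows - 1, c > 0, c < state.n_cols - 1], axis=1
        )
        nv = valid.sum(axis=1)
        k = rng.integers(0, np.maximum(nv, 1))
        d = (np.cumsum(valid, axis=1) > k[:, None]).argmax(axis=1)
        ok = move & (nv > 0)
    elif p.edge_rule == "stay":
        d = rng.integers(0, 4, n)
        nr = r + _DR[d]
        nc = c + _DC[d]
        ok = (
            move
            & (nr >= 0)
            & (nr < state.n_rows)
            & (nc >= 0)
            & (nc < state.n_cols)
        )
    else:
        raise ValueError(f"unknown edge_rule {p.edge_rule!r}")
    nr = r[ok] + _DR[d[ok]]
    nc = c[ok] + _DC[d[ok]]
    state.ad_house[idx[ok]] = nr * state.n_cols + nc
    return int(ok.sum())


def disperse_adult(
    state: GridState, adult_index: int, rng: np.random.Generator
) -> int:
    """Dispersal draw for a single adult; returns its (possibly new) house."""
    disperse_adults(state, rng, indices=np.array([adult_index]))
    return int(state.ad_house[adult_index])


def oviposit_females(
    state: GridState,
    rng: np.random.Generator,
    indices: np.ndarray | None = None,
    always: bool = False,
) -> int:
    """Oviposition by mated females; returns the number of eggs laid.

    Each laying female deposits one batch (Poisson with mean
    ``base_batch`` x her fecundity multiplier) into a container chosen
    uniformly among the accepting containers of her house; a house with no
    accepting container receives no eggs.  Offspring genotypes follow the
    Mendelian distribution of the stored mating pair; the corresponding
    hatch-survival probabilities (drive lethality x embryonic costs) are
    attached to the egg cohorts and applied at hatch.  Egg sex is assigned
    independently male/female with probability 1/2.
    """
    p = state.params
    table = state.table
    if indices is None:
        cand = state.ad_alive & (state.ad_sex == FEMALE) & state.ad_mated
        fidx = np.flatnonzero(cand)
    else:
        fidx = np.asarray(indices)
        ok = (
            state.ad_alive[fidx]
            & (state.ad_sex[fidx] == FEMALE)
            & state.ad_mated[fidx]
        )
        fidx = fidx[ok]
    if len(fidx) == 0:
        return 0
    if not always:
        fidx = fidx[rng.random(len(fidx)) < p.p_oviposit]
    if len(fidx) == 0:
        return 0
    acc_ids, acc_off = state.accepting_containers()
    fh = state.ad_house[fidx]
    n_acc = acc_off[fh + 1] - acc_off[fh]
    has = n_acc > 0
    fidx, fh, n_acc = fidx[has], fh[has], n_acc[has]
    if len(fidx) == 0:
        return 0
    pick = rng.integers(0, n_acc)
    conts = acc_ids[acc_off[fh] + pick]

    batch_mean = p.base_batch * table.fecundity[state.ad_geno[fidx]]
    batches = rng.poisson(batch_mean)
    mg = state.ad_geno[fidx]
    fg = state.ad_mate_geno[fidx]
    G = table.n_genotypes
    ncont = state.n_containers
    total = 0
    new: dict[str, list[np.ndarray]] = {
        k: [] for k in ("cont", "sex", "geno", "count", "hs")
    }
    pairs = np.unique(np.stack([mg, fg], axis=1), axis=0)
    for a, b in pairs:
        sel = (mg == a) & (fg == b)
        nb = batches[sel]
        if nb.sum() == 0:
            continue
        counts = rng.multinomial(nb, table.mendelian[a, b])  # (n_f, G)
        males = rng.binomial(counts, 0.5)
        females = counts - males
        csel = conts[sel]
        for sex, mat in ((FEMALE, females), (MALE, males)):
            key = csel[:, None] * G + np.arange(G)[None, :]
            agg = np.bincount(
                key.ravel(), weights=mat.ravel(), minlength=ncont * G
            ).astype(np.int64)
            nz = np.flatnonzero(agg)
            if len(nz) == 0:
                continue
            new["cont"].append(nz // G)
            new["geno"].append((nz % G).astype(np.int16))
            new["sex"].append(np.full(len(nz), sex, dtype=np.int8))
            new["count"].append(agg[nz])
            new["hs"].append(table.hatch_survival[a, nz % G])
            total += int(agg[nz].sum())
    if total == 0:
        return 0
    n_new = sum(len(x) for x in new["cont"])
    state.co_cont = np.concatenate([state.co_cont, *new["cont"]])
    state.co_geno = np.concatenate([state.co_geno, *new["geno"]])
    state.co_sex = np.concatenate([state.co_sex, *new["sex"]])
    state.co_count = np.concatenate([state.co_count, *new["count"]])
    state.co_hs = np.concatenate([state.co_hs, *new["hs"]])
    state.co_stage = np.concatenate(
        [state.co_stage, np.full(n_new, EGG, dtype=np.int8)]
    )
    state.co_dev = np.concatenate([state.co_dev, np.zeros(n_new)])
    state.co_mass = np.concatenate(
        [state.co_mass, np.full(n_new, p.egg_mass)]
    )
    return total


def step_day(
    state: GridState,
    env: EnvironmentDay,
    rng: np.random.Generator,
    release_events: list | None = None,
) -> DayLog:
    """Advance the whole grid by one day (fixed event order; see module doc)."""
    from .release import execute_release  # local import avoids a cycle

    log = DayLog()
    emerged = develop_immatures(state, env.temperature, rng)
    log.emerged = emerge_adults(state, emerged)
    for event in release_events or ():
        a, e = execute_release(state, event)
        log.released_adults += a
        log.released_eggs += e
    log.adult_deaths = survive_adults(state, rng)
    log.matings = mate_females(state, rng)
    disperse_adults(state, rng)
    log.eggs_laid = oviposit_females(state, rng)
    return log


# ---------------------------------------------------------------------------
# Census and initialisation helpers
# ---------------------------------------------------------------------------


def seed_population(
    state: GridState,
    rng: np.random.Generator,
    adults_per_house: int = 8,
    wildtype_index: int | None = None,
) -> int:
    """Seed a resident wildtype population in every house with a breeding site.

    Half the seeded adults are female, half male, all unmated, of mean
    size; the following burn-in year lets food supply set the equilibrium.
    """
    if wildtype_index is None:
        wildtype_index = 0  # zero transgene copies in every system encoding
    acc_ids, acc_off = state.accepting_containers()
    houses = np.unique(state.cont_house[acc_ids])
    n_f = adults_per_house // 2
    n_m = adults_per_house - n_f
    total = 0
    for sex, k in ((FEMALE, n_f), (MALE, n_m)):
        h = np.repeat(houses, k)
        state.add_adults(
            h,
            np.full(len(h), sex, dtype=np.int8),
            np.full(len(h), wildtype_index, dtype=np.int16),
        )
        total += len(h)
    return total


def genotype_counts(state: GridState, include_immatures: bool = True) -> np.ndarray:
    """Living individuals per genotype index (adults, optionally immatures)."""
    G = state.table.n_genotypes
    counts = np.bincount(
        state.ad_geno[state.ad_alive].astype(np.int64), minlength=G
    ).astype(np.int64)
    if include_immatures and len(state.co_count):
        counts += np.bincount(
            state.co_geno.astype(np.int64),
            weights=state.co_count.astype(float),
            minlength=G,
        ).astype(np.int64)
    return counts


def adult_counts_frame(state: GridState, day: int | None = None) -> pd.DataFrame:
    """Snapshot: one row per house with adult counts by sex and genotype."""
    G = state.table.n_genotypes
    labels = [g.label() for g in state.table.genotypes]
    rows = []
    alive = state.ad_alive
    key = (
        state.ad_house[alive] * (2 * G)
        + state.ad_sex[alive].astype(np.int64) * G
        + state.ad_geno[alive]
    )
    counts = np.bincount(key, minlength=state.n_houses * 2 * G).reshape(
        state.n_houses, 2, G
    )
    for h in range(state.n_houses):
        row: dict[str, object] = {
            "row": h // state.n_cols,
            "col": h % state.n_cols,
        }
        if day is not None:
            row["day"] = day
        for s, sname in ((FEMALE, "F"), (MALE, "M")):
            for g in range(G):
                row[f"{sname}_{labels[g]}"] = int(counts[h, s, g])
        rows.append(row)
    return pd.DataFrame(rows)
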