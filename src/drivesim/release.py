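"""Release programme construction and execution.

A release programme is described by the life stage released (adults or
eggs), the sex composition (male-only or both sexes), the number released
per site, the number of weekly releases, and the spatial pattern (every
house, or every tenth house in row-major order for egg releases into
"special" containers).  Releases begin after a one-year burn-in (day 365
by default) and recur weekly.

Adult releases add homozygous transgenic adults directly to houses;
released adults are one day old, of mean wildtype size, and unmated
(released females are virgin).  Egg releases create a dedicated release
container per site and event, pre-loaded with enough food for the full
cohort's larval development; the container accepts no wild oviposition,
receives no further food, and is removed from the grid as soon as all its
occupants have died or emerged — so a release never creates a breeding
site.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetics import Genotype, GeneticSystem, homozygous_construct
from .population import EGG, FEMALE, MALE, GridState

__all__ = [
    "Stage",
    "Sexes",
    "SiteRule",
    "ReleaseScenario",
    "ReleaseEvent",
    "build_schedule",
    "execute_release",
    "release_sites",
    "schedule_frame",
    "expected_adults_from_eggs",
]


class Stage(enum.Enum):
    ADULT = "adult"
    EGG = "egg"


class Sexes(enum.Enum):
    MALE_ONLY = "male_only"
    BOTH = "both"


class SiteRule(enum.Enum):
    EVERY_HOUSE = "every_house"
    EVERY_TENTH_HOUSE = "every_tenth_house"


@dataclass(frozen=True)
class ReleaseScenario:
    """Operational description of one release programme.

    ``per_site_count`` is per sex and per event for adult releases with
    both sexes, and the total egg count per site and event for egg
    releases (split equally between the sexes, since male and female eggs
    cannot be separated — egg releases therefore always deliver both
    sexes).
    """

    system: GeneticSystem
    stage: Stage = Stage.ADULT
    sexes: Sexes = Sexes.MALE_ONLY
    per_site_count: int = 1
    n_releases: int = 1
    site_rule: SiteRule = SiteRule.EVERY_HOUSE
    start_day: int = 365
    genotype: Genotype | None = None
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.per_site_count < 1 or self.n_releases < 0:
            raise ValueError(
                "per_site_count must be positive and n_releases non-negative"
            )
        if self.stage is Stage.EGG and self.sexes is not Sexes.BOTH:
            raise ValueError(
                "egg releases contain both sexes (eggs cannot be sex-sorted)"
            )
        if self.genotype is None:
            object.__setattr__(
                self, "genotype", homozygous_construct(self.system)
            )
        elif self.genotype.system is not self.system:
            raise ValueError("release genotype must match the scenario system")

    @property
    def label(self) -> str:
        if self.scenario_id:
            return self.scenario_id
        return (
            f"{self.system.value}-{self.stage.value}-{self.sexes.value}"
            f"-{self.per_site_count}x{self.n_releases}-{self.site_rule.value}"
        )


@dataclass(frozen=True)
class ReleaseEvent:
    """One release at one site on one day.

    ``sex`` is FEMALE/MALE for adult events and ``None`` for egg events
    (egg cohorts are split equally between the sexes at execution).
    """

    day: int
    house: tuple[int, int]
    stage: Stage
    sex: int | None
    genotype: Genotype
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("release count must be positive")


def release_sites(
    rule: SiteRule,
    n_rows: int,
    n_cols: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Release sites for a grid under the given spatial rule.

    ``EVERY_TENTH_HOUSE`` selects every tenth house in row-major order
    (0-based indices 9, 19, ...), i.e. ``floor(n_houses / 10)`` evenly
    spaced sites; pass an ``rng`` to sample the same number of sites
    uniformly at random instead.
    """
    n = n_rows * n_cols
    if rule is SiteRule.EVERY_HOUSE:
        idx = np.arange(n)
    else:
        k = n // 10
        if k == 0:
            raise ValueError("grid too small for a 10%-of-houses release")
        if rng is None:
            idx = np.arange(9, n, 10)
        else:
            idx = np.sort(rng.choice(n, size=k, replace=False))
    return [(int(h) // n_cols, int(h) % n_cols) for h in idx]


def build_schedule(
    scenario: ReleaseScenario,
    n_rows: int,
    n_cols: int,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReleaseEvent], dict[str, int]]:
    """Expand a scenario into per-day, per-site release events.

    Returns the event list plus an accounting dict with the total numbers
    released (``total_males``, ``total_females``, ``total_eggs``,
    ``total_individuals``, ``n_sites``).  Deterministic given the scenario
    and grid (unless a random site rule is requested via ``rng``).
    """
    sites = release_sites(scenario.site_rule, n_rows, n_cols, rng)
    if not sites:
        raise ValueError("empty release site set")
    days = [scenario.start_day + 7 * i for i in range(scenario.n_releases)]
    events: list[ReleaseEvent] = []
    for day in days:
        for house in sites:
            if scenario.stage is Stage.ADULT:
                sexes = (
                    [MALE] if scenario.sexes is Sexes.MALE_ONLY else [FEMALE, MALE]
                )
                for sex in sexes:
                    events.append(
                        ReleaseEvent(
                            day, house, Stage.ADULT, sex,
                            scenario.genotype, scenario.per_site_count,
                        )
                    )
            else:
                events.append(
                    ReleaseEvent(
                        day, house, Stage.EGG, None,
                        scenario.genotype, scenario.per_site_count,
                    )
                )
    n_sites = len(sites)
    accounting = {
        "n_sites": n_sites,
        "n_releases": scenario.n_releases,
        "total_males": 0,
        "total_females": 0,
        "total_eggs": 0,
    }
    if scenario.stage is Stage.ADULT:
        per = scenario.per_site_count * n_sites * scenario.n_releases
        accounting["total_males"] = per
        if scenario.sexes is Sexes.BOTH:
            accounting["total_females"] = per
    else:
        accounting["total_eggs"] = (
            scenario.per_site_count * n_sites * scenario.n_releases
        )
    accounting["total_individuals"] = (
        accounting["total_males"]
        + accounting["total_females"]
        + accounting["total_eggs"]
    )
    return events, accounting


def schedule_frame(events: list[ReleaseEvent]) -> pd.DataFrame:
    """Schedule as a table (day, row, col, stage, sex, count) for export."""
    return pd.DataFrame(
        {
            "day": [e.day for e in events],
            "row": [e.house[0] for e in events],
            "col": [e.house[1] for e in events],
            "stage": [e.stage.value for e in events],
            "sex": [
                {FEMALE: "F", MALE: "M", None: "both"}[e.sex] for e in events
            ],
            "count": [e.count for e in events],
        }
    )


def execute_release(state: GridState, event: ReleaseEvent) -> tuple[int, int]:
    """Apply one release event to the grid.

    Returns ``(adults_added, eggs_added)``.  Adult events append unmated
    adults of mean size aged one day.  Egg events create one fresh release
    container holding equal male and female egg cohorts of the release
    genotype, with a large finite initial food supply (enough to satisfy
    the whole cohort's larval demand) and no replenishment.
    """
    g = event.genotype.index
    if event.stage is Stage.ADULT:
        state.add_adults(
            event.house, event.sex, g,
            state.params.adult_size_mean, age=1, n=event.count,
        )
        return event.count, 0
    p = state.params
    food = event.count * p.larval_demand * p.d_larva
    cont = state.add_container(
        event.house, rate=0.0, accepts_oviposition=False,
        is_release=True, food=food,
    )
    n_female = event.count // 2
    n_male = event.count - n_female
    hs = float(state.table.hatch_survival[g, g])
    for sex, n in ((FEMALE, n_female), (MALE, n_male)):
        if n > 0:
            state.add_cohort(
                cont, EGG, sex, g, n, mass=p.egg_mass, hatch_survival=hs
            )
    return 0, event.count


def expected_adults_from_eggs(
    n_eggs: int,
    rng: np.random.Generator,
    n_sims: int = 20,
    *,
    system: GeneticSystem = GeneticSystem.WILDTYPE,
    genetic_params=None,
    lifecycle_params=None,
    temperature: float = 26.0,
    max_days: int = 200,
) -> float:
    """Mean number of adults produced by one released egg cohort.

    Monte-Carlo average over ``n_sims`` standalone simulations of a single
    release container (no resident population), used to express egg
    releases in adult-equivalents.
    """
    from .population import EnvironmentDay, develop_immatures, emerge_adults

    if n_eggs < 0:
        raise ValueError("n_eggs must be non-negative")
    if n_eggs == 0:
        return 0.0
    genotype = homozygous_construct(system)
    totals = []
    for _ in range(n_sims):
        state = GridState(
            1,
            1,
            system=system,
            genetic_params=genetic_params,
            lifecycle_params=lifecycle_params,
        )
        event = ReleaseEvent(0, (0, 0), Stage.EGG, None, genotype, n_eggs)
        execute_release(state, event)
        emerged_total = 0
        for _day in range(max_days):
            emerged = develop_immatures(state, temperature, rng)
            emerged_total += emerge_adults(state, emerged)
            if len(state.co_count) == 0:
                break
        totals.append(emerged_total)
    return float(np.mean(totals))
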