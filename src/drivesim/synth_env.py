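"""Synthetic environmental and structural inputs.

The original study area was parameterised from entomological container
surveys (153 houses, replicated four times onto a 612-house grid) and from
a five-year daily weather record at a tropical station.  This module
generates statistically similar *synthetic* stand-ins:

* a daily temperature series — seasonal sinusoid around a tropical mean
  with Gaussian day-to-day noise;
* per-house container profiles — the number of containers per house is
  drawn from a zero-inflated negative binomial (container surveys are
  overdispersed, with many container-free houses) and each container gets
  a lognormal daily food-supply rate.  Each synthetic surveyed profile is
  instantiated ``replication``-fold at randomly permuted grid positions,
  mirroring the survey-replication construction of the original area.

The distributional shapes and parameters are configurable stand-ins, not
claims about any real city.  All generators are pure functions of their
parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetics import GeneticParams, GeneticSystem
from .population import EnvironmentDay, GridState, LifecycleParams

__all__ = [
    "WeatherModel",
    "ContainerSurveyModel",
    "generate_temperatures",
    "generate_temperature_series",
    "draw_house_profiles",
    "generate_study_area",
    "make_fixture",
]


@dataclass(frozen=True)
class WeatherModel:
    """Sinusoid-plus-noise daily temperature generator (degrees Celsius)."""

    mean: float = 26.0
    amplitude: float = 1.5
    period: float = 365.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be non-negative")


def generate_temperatures(model: WeatherModel, n_days: int) -> np.ndarray:
    """Daily mean temperatures as an array of length ``n_days``."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(model.seed)
    t = np.arange(n_days)
    series = model.mean + model.amplitude * np.sin(2.0 * np.pi * t / model.period)
    if model.noise_sd > 0:
        series = series + rng.normal(0.0, model.noise_sd, n_days)
    return series


def generate_temperature_series(
    model: WeatherModel, n_days: int
) -> list[EnvironmentDay]:
    """The temperature series wrapped as per-day environment records."""
    return [
        EnvironmentDay(temperature=float(x), day_index=i)
        for i, x in enumerate(generate_temperatures(model, n_days))
    ]


@dataclass(frozen=True)
class ContainerSurveyModel:
    """Generator of heterogeneous per-house container profiles.

    ``p_zero`` is the extra zero-inflation mass (houses with no
    containers); conditional on not being structurally zero, the container
    count is negative binomial with the given mean and shape.  Each
    container's daily food-supply rate is lognormal with the given median
    and log-scale sigma (mass units per day; one mass unit is one
    well-fed adult's larval intake over roughly a day).
    """

    n_surveyed_houses: int = 153
    replication: int = 4
    p_zero: float = 0.2
    nb_mean: float = 2.0
    nb_shape: float = 2.0
    rate_median: float = 2.0
    rate_log_sd: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replication < 1:
            raise ValueError("replication factor must be >= 1")
        if not 0.0 <= self.p_zero < 1.0:
            raise ValueError("p_zero must be in [0, 1)")
        if self.nb_mean <= 0 or self.nb_shape <= 0 or self.rate_median <= 0:
            raise ValueError("distribution parameters must be positive")


def draw_house_profiles(
    model: ContainerSurveyModel, rng: np.random.Generator
) -> list[list[float]]:
    """One synthetic survey: a list of per-house container food-rate lists."""
    n = model.n_surveyed_houses
    zero = rng.random(n) < model.p_zero
    # NB parameterised by mean/shape: p = shape / (shape + mean)
    p = model.nb_shape / (model.nb_shape + model.nb_mean)
    counts = rng.negative_binomial(model.nb_shape, p, n)
    counts[zero] = 0
    profiles = []
    for c in counts:
        rates = model.rate_median * np.exp(
            rng.normal(0.0, model.rate_log_sd, int(c))
        )
        profiles.append([float(r) for r in rates])
    return profiles


def generate_study_area(
    survey: ContainerSurveyModel,
    n_rows: int,
    n_cols: int,
    *,
    system: GeneticSystem = GeneticSystem.WILDTYPE,
    genetic_params: GeneticParams | None = None,
    lifecycle_params: LifecycleParams | None = None,
) -> GridState:
    """Build a grid by replicating synthetic surveyed house profiles.

    Draws ``n_surveyed_houses`` profiles, instantiates each exactly
    ``replication`` times, and scatters them over randomly permuted grid
    positions.  The grid must hold at least
    ``n_surveyed_houses * replication`` houses; any surplus positions are
    container-free houses.
    """
    total = survey.n_surveyed_houses * survey.replication
    if n_rows * n_cols < total:
        raise ValueError(
            f"grid capacity {n_rows * n_cols} below "
            f"{survey.n_surveyed_houses} x {survey.replication} = {total}"
        )
    rng = np.random.default_rng(survey.seed)
    profiles = draw_house_profiles(survey, rng)
    state = GridState(
        n_rows,
        n_cols,
        system=system,
        genetic_params=genetic_params,
        lifecycle_params=lifecycle_params,
    )
    positions = rng.permutation(n_rows * n_cols)[:total]
    k = 0
    for profile in profiles:
        for _ in range(survey.replication):
            house = int(positions[k])
            k += 1
            for rate in profile:
                state.add_container(house, rate=rate)
    return state


def study_area_frame(state: GridState) -> pd.DataFrame:
    """Container layout as a table (house row/col, container id, food rate)."""
    return pd.DataFrame(
        {
            "row": state.cont_house // state.n_cols,
            "col": state.cont_house % state.n_cols,
            "container": np.arange(state.n_containers),
            "food_rate": state.cont_rate,
            "accepts_oviposition": state.cont_accepts,
        }
    )


def make_fixture(
    name: str,
    *,
    system: GeneticSystem = GeneticSystem.WILDTYPE,
    genetic_params: GeneticParams | None = None,
    lifecycle_params: LifecycleParams | None = None,
    seed: int = 0,
) -> tuple[GridState, WeatherModel, LifecycleParams]:
    """Deterministic study-area fixtures for tests and scaled-down sweeps.

    ``tiny``: 3x3 grid, one container per house.  ``single_house``: one
    house with one effectively unlimited container (panmictic harness for
    oracle comparisons).  ``mid``: 20x20 grid built from a 100-house
    synthetic survey replicated 4 times (scaled-down analogue of the full
    612-house area).
    """
    lparams = lifecycle_params or LifecycleParams()
    weather = WeatherModel(seed=seed)
    if name == "tiny":
        state = GridState(
            3, 3, system=system,
            genetic_params=genetic_params, lifecycle_params=lparams,
        )
        for h in range(9):
            state.add_container(h, rate=2.0)
    elif name == "single_house":
        state = GridState(
            1, 1, system=system,
            genetic_params=genetic_params, lifecycle_params=lparams,
        )
        state.add_container(0, rate=1e9, food=1e12)
    elif name == "mid":
        survey = ContainerSurveyModel(
            n_surveyed_houses=100, replication=4, seed=seed
        )
        state = generate_study_area(
            survey, 20, 20, system=system,
            genetic_params=genetic_params, lifecycle_params=lparams,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return state, weather, lparams
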