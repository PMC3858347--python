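"""Generation-synchronised single-house harness.

The deterministic recursions in :mod:`drivesim.oracle` use non-overlapping
generations, while the spatial engine is daily with overlapping ages.  To
validate the engine's genetic bookkeeping against the recursions, this
harness runs the simulator's own mating machinery in a panmictic single
house and forces discrete generations: every adult reproduces in exactly
one round and is then replaced by a fixed-size sample of its offspring
pool.  This isolates the genetic logic (segregation, maternal-effect
lethality, KR viability, fitness costs, size-weighted monogamous mating)
from demography.
"""

from __future__ import annotations

import numpy as np

from .genetics import GeneticParams, GeneticSystem
from .population import FEMALE, MALE, GridState, LifecycleParams, mate_females

__all__ = ["discrete_generation_run"]


def discrete_generation_run(
    system: GeneticSystem,
    genetic_params: GeneticParams,
    initial_genotype_counts: np.ndarray,
    n_generations: int,
    rng: np.random.Generator,
    *,
    pop_size: int | None = None,
    batch_mean: float = 50.0,
) -> np.ndarray:
    """Run discrete, panmictic generations with the engine's genetic rules.

    ``initial_genotype_counts`` gives the adult count per genotype index
    (split equally between the sexes).  Each generation, every female
    mates once (size-weighted, all sizes equal here), lays a Poisson batch
    scaled by her fecundity multiplier, offspring genotypes follow the
    pair's Mendelian distribution thinned by hatch survival (drive
    lethality times embryonic costs), and the next generation is a
    without-replacement sample of ``pop_size`` offspring.

    Returns the genotype-count trajectory, shape
    ``(n_generations + 1, n_genotypes)``; rows may sum to less than
    ``pop_size`` if the offspring pool is smaller.
    """
    counts = np.asarray(initial_genotype_counts, dtype=np.int64)
    if pop_size is None:
        pop_size = int(counts.sum())
    state = GridState(1, 1, system=system, genetic_params=genetic_params)
    table = state.table
    G = table.n_genotypes
    if len(counts) != G:
        raise ValueError("initial counts must have one entry per genotype")
    traj = np.empty((n_generations + 1, G), dtype=np.int64)
    traj[0] = counts
    for gen in range(n_generations):
        _set_adults(state, counts)
        mate_females(state, rng)
        mated = state.ad_alive & (state.ad_sex == FEMALE) & state.ad_mated
        fidx = np.flatnonzero(mated)
        pool = np.zeros(G, dtype=np.int64)
        if len(fidx):
            mg = state.ad_geno[fidx]
            fg = state.ad_mate_geno[fidx]
            pairs, pair_n = np.unique(
                np.stack([mg, fg], axis=1), axis=0, return_counts=True
            )
            for (a, b), n_pairs in zip(pairs, pair_n):
                batches = rng.poisson(
                    batch_mean * table.fecundity[a], n_pairs
                )
                eggs = rng.multinomial(int(batches.sum()), table.mendelian[a, b])
                survivors = rng.binomial(eggs, table.hatch_survival[a])
                pool += survivors
        total = int(pool.sum())
        if total == 0:
            traj[gen + 1 :] = 0
            return traj
        if total > pop_size:
            counts = rng.multivariate_hypergeometric(pool, pop_size)
        else:
            counts = pool
        counts = np.asarray(counts, dtype=np.int64)
        traj[gen + 1] = counts
    return traj


def _set_adults(state: GridState, counts: np.ndarray) -> None:
    """Replace the house's adults with fresh unmated ones (half per sex)."""
    n = int(counts.sum())
    genos = np.repeat(np.arange(len(counts), dtype=np.int16), counts)
    sexes = np.empty(n, dtype=np.int8)
    # alternate sexes within each genotype so the split is as even as possible
    sexes[0::2] = FEMALE
    sexes[1::2] = MALE
    state.ad_house = np.zeros(n, dtype=np.int64)
    state.ad_sex = sexes
    state.ad_geno = genos
    state.ad_size = np.full(n, state.params.adult_size_mean)
    state.ad_age = np.zeros(n, dtype=np.int32)
    state.ad_mated = np.zeros(n, dtype=bool)
    state.ad_mate_geno = np.full(n, -1, dtype=np.int16)
    state.ad_alive = np.ones(n, dtype=bool)
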