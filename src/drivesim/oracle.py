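"""Deterministic panmictic recursions for Medea and Killer-Rescue dynamics.

These are the infinite-population, discrete-generation, random-mating
limits of the stochastic engine.  They serve two purposes: as correctness
oracles for the genetic bookkeeping of the simulator (the two must agree in
the large-N single-house limit), and as fast explorers of release-threshold
behaviour.

The Medea recursion tracks genotype frequencies at the single Medea locus;
because the maternal toxin acts on the mother's *genotype*, a full mating
table (not just gamete pools) is contracted each generation.  The female
fecundity cost enters as a weight on a mother's chance of being the dam of
a random offspring — the deterministic analogue of scaling her batch size.

The KR recursion tracks the four gamete frequencies {kr, kR, Kr, KR} so
linkage disequilibrium between the two unlinked loci is carried exactly;
genotypes are formed by random union of gametes, weighted by viability and
embryonic costs, and gamete output uses free recombination (within an
individual the two loci segregate independently).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genetics import GeneticParams, GeneticSystem, GenotypeTable

__all__ = [
    "MedeaState",
    "KRState",
    "ExtinctionError",
    "medea_next_generation",
    "kr_next_generation",
    "medea_release_threshold",
    "medea_trajectory",
    "kr_trajectory",
]

#: gamete order for the KR recursion: index = 2*has_K + has_R
KR_GAMETES = ("kr", "kR", "Kr", "KR")


class ExtinctionError(RuntimeError):
    """Raised when a recursion step leaves no surviving offspring."""


@dataclass(frozen=True)
class MedeaState:
    """Genotype frequencies (f_mm, f_Mm, f_MM), normalised."""

    f_mm: float
    f_Mm: float
    f_MM: float

    def __post_init__(self) -> None:
        arr = self.as_array()
        if (arr < -1e-12).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("genotype frequencies must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        # indexed by M copy number, matching Genotype.index
        return np.array([self.f_mm, self.f_Mm, self.f_MM])

    @classmethod
    def from_array(cls, f: np.ndarray) -> "MedeaState":
        return cls(float(f[0]), float(f[1]), float(f[2]))

    @classmethod
    def hardy_weinberg(cls, f_M: float) -> "MedeaState":
        q = 1.0 - f_M
        return cls(q * q, 2.0 * f_M * q, f_M * f_M)

    @property
    def f_M(self) -> float:
        return 0.5 * self.f_Mm + self.f_MM


@dataclass(frozen=True)
class KRState:
    """Gamete frequencies over {kr, kR, Kr, KR}, normalised (carries LD)."""

    gametes: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        arr = self.as_array()
        if (arr < -1e-12).any() or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError("gamete frequencies must be non-negative and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.gametes, dtype=float)

    @classmethod
    def from_array(cls, x: np.ndarray) -> "KRState":
        return cls(tuple(float(v) for v in x))

    @classmethod
    def from_allele_frequencies(cls, f_K: float, f_R: float) -> "KRState":
        """Linkage-equilibrium state at the given allele frequencies."""
        return cls(
            (
                (1 - f_K) * (1 - f_R),
                (1 - f_K) * f_R,
                f_K * (1 - f_R),
                f_K * f_R,
            )
        )

    @property
    def f_K(self) -> float:
        return self.gametes[2] + self.gametes[3]

    @property
    def f_R(self) -> float:
        return self.gametes[1] + self.gametes[3]

    def genotype_frequencies(self) -> np.ndarray:
        """Zygote frequencies (length 9, Genotype.index order) by random union."""
        x = self.as_array()
        f9 = np.zeros(9)
        for i in range(4):
            for j in range(4):
                k = (i >> 1) + (j >> 1)
                r = (i & 1) + (j & 1)
                f9[3 * k + r] += x[i] * x[j]
        return f9


# ---------------------------------------------------------------------------
# Medea recursion
# ---------------------------------------------------------------------------


def _medea_step(f: np.ndarray, table: GenotypeTable) -> np.ndarray:
    """One generation on a raw genotype-frequency vector (length 3)."""
    mother_w = f * table.fecundity
    tot = mother_w.sum()
    if tot <= 0.0:
        raise ExtinctionError("no reproducing mothers")
    mother_p = mother_w / tot
    # joint over (mother, father, offspring), weighted by hatch survival
    surv = np.einsum(
        "i,j,ijk,ik->k", mother_p, f, table.mendelian, table.hatch_survival
    )
    total = surv.sum()
    if total <= 0.0:
        raise ExtinctionError("no surviving offspring")
    return surv / total


def medea_next_generation(state: MedeaState, params: GeneticParams) -> MedeaState:
    """Advance the Medea genotype-frequency recursion by one generation."""
    table = GenotypeTable(GeneticSystem.MEDEA, params)
    return MedeaState.from_array(_medea_step(state.as_array(), table))


def medea_trajectory(
    state: MedeaState, params: GeneticParams, n_generations: int
) -> np.ndarray:
    """Genotype-frequency trajectory, shape ``(n_generations + 1, 3)``."""
    table = GenotypeTable(GeneticSystem.MEDEA, params)
    f = state.as_array()
    out = np.empty((n_generations + 1, 3))
    out[0] = f
    for g in range(n_generations):
        f = _medea_step(f, table)
        out[g + 1] = f
    return out


# ---------------------------------------------------------------------------
# KR recursion
# ---------------------------------------------------------------------------

# map gamete pair -> genotype index, and genotype -> gamete output
_G9 = np.zeros((4, 4, 9))
for _i in range(4):
    for _j in range(4):
        _G9[_i, _j, 3 * ((_i >> 1) + (_j >> 1)) + (_i & 1) + (_j & 1)] = 1.0

_GAMETE_OUT = np.zeros((9, 4))
for _g in range(9):
    _k, _r = _g // 3, _g % 3
    for _i in range(4):
        _pk = _k / 2.0 if (_i >> 1) else 1.0 - _k / 2.0
        _pr = _r / 2.0 if (_i & 1) else 1.0 - _r / 2.0
        _GAMETE_OUT[_g, _i] = _pk * _pr


def _kr_step(x: np.ndarray, viability: np.ndarray) -> np.ndarray:
    """One generation on a raw gamete-frequency vector (length 4)."""
    f9 = np.einsum("i,j,ijg->g", x, x, _G9)
    fw = f9 * viability
    total = fw.sum()
    if total <= 0.0:
        raise ExtinctionError("no surviving offspring")
    fw /= total
    y = fw @ _GAMETE_OUT
    return y / y.sum()


def _kr_viability(params: GeneticParams) -> np.ndarray:
    table = GenotypeTable(GeneticSystem.KR, params)
    # hatch survival is mother-independent for KR; any mother row works
    return table.hatch_survival[0].copy()


def kr_next_generation(state: KRState, params: GeneticParams) -> KRState:
    """Advance the KR gamete-frequency recursion by one generation."""
    return KRState.from_array(_kr_step(state.as_array(), _kr_viability(params)))


def kr_trajectory(
    state: KRState, params: GeneticParams, n_generations: int
) -> np.ndarray:
    """Gamete-frequency trajectory, shape ``(n_generations + 1, 4)``."""
    v = _kr_viability(params)
    x = state.as_array()
    out = np.empty((n_generations + 1, 4))
    out[0] = x
    for g in range(n_generations):
        x = _kr_step(x, v)
        out[g + 1] = x
    return out


# ---------------------------------------------------------------------------
# Release threshold
# ---------------------------------------------------------------------------


def _medea_fixes(
    f0: float, table: GenotypeTable, max_generations: int = 2000
) -> bool:
    """Does a Hardy-Weinberg release at frequency f0 spread to fixation?

    'Fixation' here means escaping above the unstable internal equilibrium
    created by the embryonic cost: the allele then climbs to its high
    stable state (exactly 1 when the cost is zero; slightly below 1 for a
    per-copy cost, which protects rare wild-type alleles in heterozygotes).
    Below the threshold the allele frequency decays instead.
    """
    f = MedeaState.hardy_weinberg(f0).as_array()
    f_M = f0
    for _ in range(max_generations):
        f = _medea_step(f, table)
        f_M = 0.5 * f[1] + f[2]
        if f_M > 0.999:
            return True
        if f_M < max(1e-12, 1e-3 * f0):
            return False
    return f_M > f0


def medea_release_threshold(
    params: GeneticParams,
    tolerance: float = 1e-4,
    max_iterations: int = 60,
    max_generations: int = 2000,
) -> float:
    """Critical post-release M frequency above which Medea fixes.

    Bisection on the initial (Hardy-Weinberg) allele frequency of the
    deterministic recursion.  A cost-free element fixes from any positive
    frequency, so the threshold is 0; embryonic costs create an unstable
    internal equilibrium and the threshold rises with c_M.
    """
    if not 0.0 <= params.c_M < 1.0:
        raise ValueError("threshold defined for c_M in [0, 1)")
    table = GenotypeTable(GeneticSystem.MEDEA, params)
    lo, hi = 0.0, 1.0
    f_probe = max(tolerance / 10.0, 1e-6)
    if _medea_fixes(f_probe, table, max_generations):
        return 0.0
    if not _medea_fixes(1.0 - 1e-6, table, max_generations):
        raise RuntimeError("no fixing release frequency found below 1")
    lo = f_probe
    for _ in range(max_iterations):
        if hi - lo <= tolerance:
            return 0.5 * (lo + hi)
        mid = 0.5 * (lo + hi)
        if _medea_fixes(mid, table, max_generations):
            hi = mid
        else:
            lo = mid
    raise RuntimeError("bisection failed to converge within iteration cap")
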