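"""Genetic logic for Medea and Killer-Rescue (KR) constructs.

Two engineered gene-drive systems are modelled, each built on simple
Mendelian inheritance of autosomal biallelic loci:

* **Medea** — a single locus with a transgenic allele ``M`` (carrying the
  anti-pathogen cargo) and a wild-type allele ``m``.  Mothers bearing at
  least one ``M`` copy deposit a toxin in every embryo; embryos that do not
  inherit an ``M`` copy from either parent cannot express the antidote and
  die (with probability ``medea_lethality``, complete by default).  Carrying
  the construct may impose an embryonic viability cost ``c_M`` per copy and
  a dominant female-specific fecundity cost ``c_F``.

* **Killer-Rescue (KR)** — two unlinked loci.  A killer allele ``K`` is
  unconditionally lethal (dominant, complete) unless the individual also
  carries at least one copy of the unlinked rescue allele ``R`` (dominant,
  complete rescue).  Each transgene copy may impose an embryonic viability
  cost (``c_K``, ``c_R``); overall fitness is multiplicative across loci.
  No fecundity cost is modelled for KR.

Embryonic costs and drive lethality act at egg hatch as an extra mortality
factor; the fecundity cost scales the mean size of a mother's egg batches.

The functions in this module are pure and enumerative (dictionaries over
:class:`Genotype`), serving as the single source of truth for the genetic
rules.  :class:`GenotypeTable` packs them into dense numpy tensors for the
vectorised population engine and the deterministic recursion oracles.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticSystem",
    "Genotype",
    "GeneticParams",
    "GenotypeTable",
    "gamete_distribution",
    "medea_embryo_survives",
    "kr_viable",
    "embryonic_cost_multiplier",
    "fecundity_multiplier",
    "offspring_survival_distribution",
]


class GeneticSystem(enum.Enum):
    """Which engineered loci are active in a running scenario."""

    MEDEA = "medea"
    KR = "kr"
    WILDTYPE = "wildtype"


@dataclass(frozen=True)
class Genotype:
    """Allele copy counts at the loci relevant to one genetic system.

    Genotypes are stored as unordered copy counts; the model has no
    parent-of-origin effect other than the maternal Medea toxin, which
    depends only on the mother's own genotype.
    """

    system: GeneticSystem
    medea_copies: int = 0
    k_copies: int = 0
    r_copies: int = 0

    def __post_init__(self) -> None:
        for name in ("medea_copies", "k_copies", "r_copies"):
            v = getattr(self, name)
            if v not in (0, 1, 2):
                raise ValueError(f"{name}={v!r} not in {{0,1,2}}")
        if self.system is GeneticSystem.MEDEA and (self.k_copies or self.r_copies):
            raise ValueError("Medea-scenario genotype cannot carry K or R alleles")
        if self.system is GeneticSystem.KR and self.medea_copies:
            raise ValueError("KR-scenario genotype cannot carry M alleles")
        if self.system is GeneticSystem.WILDTYPE and (
            self.medea_copies or self.k_copies or self.r_copies
        ):
            raise ValueError("wildtype-only genotype cannot carry transgenes")

    # -- integer encoding used by the vectorised engine -------------------
    @property
    def index(self) -> int:
        if self.system is GeneticSystem.MEDEA:
            return self.medea_copies
        if self.system is GeneticSystem.KR:
            return 3 * self.k_copies + self.r_copies
        return 0

    @classmethod
    def from_index(cls, system: GeneticSystem, index: int) -> "Genotype":
        if system is GeneticSystem.MEDEA:
            return cls(system, medea_copies=index)
        if system is GeneticSystem.KR:
            return cls(system, k_copies=index // 3, r_copies=index % 3)
        if index != 0:
            raise ValueError("wildtype system has a single genotype")
        return cls(system)

    def copies(self, allele: str) -> int:
        return {"M": self.medea_copies, "K": self.k_copies, "R": self.r_copies}[allele]

    def label(self) -> str:
        """Human-readable genotype string, e.g. ``'Mm'`` or ``'KkRr'``."""
        if self.system is GeneticSystem.MEDEA:
            return "M" * self.medea_copies + "m" * (2 - self.medea_copies)
        if self.system is GeneticSystem.KR:
            return (
                "K" * self.k_copies
                + "k" * (2 - self.k_copies)
                + "R" * self.r_copies
                + "r" * (2 - self.r_copies)
            )
        return "++"


def homozygous_construct(system: GeneticSystem) -> Genotype:
    """The transgenic release genotype: MM, or KKRR, for the active system."""
    if system is GeneticSystem.MEDEA:
        return Genotype(system, medea_copies=2)
    if system is GeneticSystem.KR:
        return Genotype(system, k_copies=2, r_copies=2)
    return Genotype(system)


def wildtype(system: GeneticSystem) -> Genotype:
    return Genotype(system)


@dataclass(frozen=True)
class GeneticParams:
    """Fitness-cost and lethality parameters.

    c_M : embryonic viability cost per Medea construct copy.
    c_F : dominant female-specific fecundity cost of carrying Medea.
    c_K, c_R : embryonic viability costs per K / R copy.
    medea_lethality : mortality of non-Medea offspring of a Medea-bearing
        mother (complete, 1.0, by default; the parameter is exposed because
        intermediate toxin efficiencies are biologically plausible).
    """

    c_M: float = 0.0
    c_F: float = 0.1
    c_K: float = 0.0
    c_R: float = 0.0
    medea_lethality: float = 1.0

    def __post_init__(self) -> None:
        for name in ("c_M", "c_F", "c_K", "c_R", "medea_lethality"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _require_system(g: Genotype, *allowed: GeneticSystem) -> None:
    if g.system not in allowed:
        raise ValueError(f"operation not defined for {g.system} genotypes")


def gamete_distribution(parent: Genotype) -> dict[str, float]:
    """Mendelian gamete distribution of a parent.

    Loci segregate independently (the K and R loci are unlinked), so a
    double heterozygote produces all four gamete classes at 1/4 each.
    Gametes are keyed by allele strings, e.g. ``'M'``, ``'kR'``.
    """
    if parent.system is GeneticSystem.MEDEA:
        p_M = parent.medea_copies / 2.0
        out = {"M": p_M, "m": 1.0 - p_M}
    elif parent.system is GeneticSystem.KR:
        p_K = parent.k_copies / 2.0
        p_R = parent.r_copies / 2.0
        out = {}
        for k_sym, pk in (("K", p_K), ("k", 1.0 - p_K)):
            for r_sym, pr in (("R", p_R), ("r", 1.0 - p_R)):
                out[k_sym + r_sym] = pk * pr
    else:
        out = {"+": 1.0}
    return {g: p for g, p in out.items() if p > 0.0}


def medea_embryo_survives(
    mother: Genotype, offspring: Genotype, params: GeneticParams
) -> float:
    """Survival probability of an embryo under Medea maternal-effect action.

    A mother carrying at least one M copy loads the toxin into every embryo;
    embryos without an M copy of their own cannot make the antidote and die
    with probability ``medea_lethality``.
    """
    _require_system(mother, GeneticSystem.MEDEA, GeneticSystem.WILDTYPE)
    _require_system(offspring, GeneticSystem.MEDEA, GeneticSystem.WILDTYPE)
    if mother.medea_copies >= 1 and offspring.medea_copies == 0:
        return 1.0 - params.medea_lethality
    return 1.0


def kr_viable(offspring: Genotype) -> bool:
    """KR viability rule: K kills (dominant, complete) unless R rescues."""
    _require_system(offspring, GeneticSystem.KR, GeneticSystem.WILDTYPE)
    return not (offspring.k_copies >= 1 and offspring.r_copies == 0)


def embryonic_cost_multiplier(offspring: Genotype, params: GeneticParams) -> float:
    """Per-copy embryonic viability multiplier, multiplicative across loci.

    Medea: (1-c_M)^copies.  KR: (1-c_K)^k * (1-c_R)^r.  Applied at hatch
    as extra mortality on newly hatched eggs.
    """
    if offspring.system is GeneticSystem.MEDEA:
        return (1.0 - params.c_M) ** offspring.medea_copies
    if offspring.system is GeneticSystem.KR:
        return (1.0 - params.c_K) ** offspring.k_copies * (
            1.0 - params.c_R
        ) ** offspring.r_copies
    return 1.0


def fecundity_multiplier(mother: Genotype, params: GeneticParams) -> float:
    """Scaling of mean egg-batch size for a mother of the given genotype.

    The Medea fecundity cost c_F is dominant and female-specific: carriers
    (Mm or MM) lay batches reduced by the same factor.  KR mothers carry no
    fecundity cost.
    """
    if mother.system is GeneticSystem.MEDEA and mother.medea_copies >= 1:
        return 1.0 - params.c_F
    return 1.0


def _union(system: GeneticSystem, g1: str, g2: str) -> Genotype:
    """Offspring genotype from two gamete strings."""
    alleles = g1 + g2
    if system is GeneticSystem.MEDEA:
        return Genotype(system, medea_copies=alleles.count("M"))
    if system is GeneticSystem.KR:
        return Genotype(
            system, k_copies=alleles.count("K"), r_copies=alleles.count("R")
        )
    return Genotype(system)


def offspring_survival_distribution(
    mother: Genotype, father: Genotype, params: GeneticParams
) -> dict[Genotype, tuple[float, float]]:
    """Offspring genotype distribution of a mating pair, with hatch survival.

    Returns ``{offspring: (mendelian_probability, hatch_survival)}`` where
    the Mendelian probabilities sum to 1 over the brood and hatch survival
    combines drive-induced lethality with embryonic fitness costs.  No
    renormalisation is applied: drive lethality shrinks the brood rather
    than redistributing it.
    """
    if mother.system is not father.system:
        raise ValueError("parents must belong to the same genetic system")
    out: dict[Genotype, list[float]] = {}
    for gm, pm in gamete_distribution(mother).items():
        for gf, pf in gamete_distribution(father).items():
            child = _union(mother.system, gm, gf)
            out.setdefault(child, [0.0])[0] += pm * pf
    dist: dict[Genotype, tuple[float, float]] = {}
    for child, (p,) in out.items():
        if mother.system is GeneticSystem.KR:
            drive = 1.0 if kr_viable(child) else 0.0
        else:
            drive = medea_embryo_survives(mother, child, params)
        surv = drive * embryonic_cost_multiplier(child, params)
        dist[child] = (p, surv)
    return dist


@dataclass
class GenotypeTable:
    """Dense tensor view of the genetic rules for one system.

    Attributes
    ----------
    genotypes : list of all genotypes, ordered by :attr:`Genotype.index`.
    mendelian : ``(n, n, n)`` array; ``mendelian[i, j, k]`` is the Mendelian
        probability that a mother of genotype ``i`` and father ``j`` produce
        an offspring of genotype ``k``.
    hatch_survival : ``(n, n)`` array; ``hatch_survival[i, k]`` is the
        probability that a genotype-``k`` egg of a genotype-``i`` mother
        survives hatch (drive lethality times embryonic costs).
    fecundity : ``(n,)`` array of batch-size multipliers by mother genotype.
    """

    system: GeneticSystem
    params: GeneticParams
    genotypes: list[Genotype] = field(init=False)
    mendelian: np.ndarray = field(init=False)
    hatch_survival: np.ndarray = field(init=False)
    fecundity: np.ndarray = field(init=False)
    copies: dict[str, np.ndarray] = field(init=False)

    def __post_init__(self) -> None:
        n = {GeneticSystem.MEDEA: 3, GeneticSystem.KR: 9, GeneticSystem.WILDTYPE: 1}[
            self.system
        ]
        self.genotypes = [Genotype.from_index(self.system, i) for i in range(n)]
        self.mendelian = np.zeros((n, n, n))
        self.hatch_survival = np.ones((n, n))
        self.fecundity = np.array(
            [fecundity_multiplier(g, self.params) for g in self.genotypes]
        )
        for i, j in itertools.product(range(n), range(n)):
            dist = offspring_survival_distribution(
                self.genotypes[i], self.genotypes[j], self.params
            )
            for child, (p, _s) in dist.items():
                self.mendelian[i, j, child.index] = p
        for i, k in itertools.product(range(n), range(n)):
            mother, child = self.genotypes[i], self.genotypes[k]
            if self.system is GeneticSystem.KR:
                drive = 1.0 if kr_viable(child) else 0.0
            else:
                drive = medea_embryo_survives(mother, child, self.params)
            self.hatch_survival[i, k] = drive * embryonic_cost_multiplier(
                child, self.params
            )
        self.copies = {
            a: np.array([g.copies(a) for g in self.genotypes], dtype=float)
            for a in ("M", "K", "R")
        }

    @property
    def n_genotypes(self) -> int:
        return len(self.genotypes)

    def allele_frequency(self, counts: np.ndarray, allele: str) -> float:
        """Allele frequency in a vector of per-genotype individual counts."""
        total = counts.sum()
        if total == 0:
            return 0.0
        return float((counts * self.copies[allele]).sum() / (2.0 * total))
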