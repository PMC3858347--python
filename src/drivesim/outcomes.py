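"""Allele-frequency tracking, outcome classification and replicate summaries.

A release programme is judged by the frequency of the cargo-bearing allele
(M for Medea, R — and K — for Killer-Rescue) three years after the first
release.  Terminal outcomes fall in four classes: full spread (f > 0.8),
partial spread (0.2 < f < 0.8), no spread (0 < f < 0.2) and lost (f = 0).
The boundary values 0.2 and 0.8, unassigned by the strict inequalities,
are counted as partial spread (configurable via ``classify_outcome``).

Frequencies are censused over all living individuals, immatures included,
by default; an adults-only census is available since either convention is
defensible.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import GridState, genotype_counts

__all__ = [
    "TerminalClass",
    "OutcomeRecord",
    "ReplicateSummary",
    "allele_frequency",
    "classify_outcome",
    "rr_fraction",
    "summarize",
]


class TerminalClass(enum.Enum):
    FULL_SPREAD = "full_spread"
    PARTIAL_SPREAD = "partial_spread"
    NO_SPREAD = "no_spread"
    LOST = "lost"


def allele_frequency(
    state: GridState, allele: str, *, include_immatures: bool = True
) -> float:
    """Population frequency of a transgenic allele (M, K or R).

    Copies of the allele over all living individuals divided by two times
    the number of individuals.  An extinct population reports 0 (check
    population size separately to distinguish loss from extinction).
    """
    counts = genotype_counts(state, include_immatures=include_immatures)
    return state.table.allele_frequency(counts.astype(float), allele)


def classify_outcome(
    f: float, *, boundary_class: TerminalClass = TerminalClass.PARTIAL_SPREAD
) -> TerminalClass:
    """Terminal outcome class of a final allele frequency."""
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"frequency {f} outside [0, 1]")
    if f == 0.0:
        return TerminalClass.LOST
    if f > 0.8:
        return TerminalClass.FULL_SPREAD
    if f < 0.2:
        return TerminalClass.NO_SPREAD
    if f in (0.2, 0.8):
        return boundary_class
    return TerminalClass.PARTIAL_SPREAD


def rr_fraction(
    source: GridState | float, mode: str = "random_mating"
) -> float:
    """Fraction of rr individuals (no rescue allele; can transmit disease).

    ``mode='random_mating'`` treats ``source`` as the R allele frequency
    and returns the Hardy-Weinberg proportion (1 - f_R)^2.
    ``mode='empirical'`` counts rr genotypes directly in a KR grid state.
    """
    if mode == "random_mating":
        if isinstance(source, GridState):
            f = allele_frequency(source, "R")
        else:
            f = float(source)
        return (1.0 - f) ** 2
    if mode == "empirical":
        if not isinstance(source, GridState):
            raise TypeError("empirical mode requires a grid state")
        counts = genotype_counts(source).astype(float)
        total = counts.sum()
        if total == 0:
            return 0.0
        r_copies = source.table.copies["R"]
        return float(counts[r_copies == 0].sum() / total)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class OutcomeRecord:
    """One replicate: daily allele-frequency trajectory plus terminal class.

    ``trajectory`` has columns day, f_M, f_K, f_R, n_adults, n_immature.
    ``checkpoints`` maps years-since-first-release to the construct
    frequency then (1-, 2- and 3-year evaluations).
    """

    scenario_id: str
    replicate: int
    seed: int
    trajectory: pd.DataFrame
    terminal_class: TerminalClass
    terminal_day: int
    terminal_frequency: float
    checkpoints: dict[int, float] = field(default_factory=dict)


@dataclass
class ReplicateSummary:
    """Outcome-class proportions and terminal-frequency moments."""

    scenario_id: str
    n_replicates: int
    proportions: dict[TerminalClass, float]
    mean_terminal_frequency: float
    sd_terminal_frequency: float

    def as_row(self) -> dict[str, object]:
        row: dict[str, object] = {
            "scenario_id": self.scenario_id,
            "n_replicates": self.n_replicates,
        }
        for cls in TerminalClass:
            row[f"p_{cls.value}"] = self.proportions[cls]
        row["mean_terminal_frequency"] = self.mean_terminal_frequency
        row["sd_terminal_frequency"] = self.sd_terminal_frequency
        return row


def summarize(records: list[OutcomeRecord]) -> ReplicateSummary:
    """Collapse a replicate set into class proportions and mean +/- SD."""
    if not records:
        raise ValueError("cannot summarize an empty replicate set")
    ids = {r.scenario_id for r in records}
    if len(ids) != 1:
        raise ValueError(f"records span multiple scenarios: {sorted(ids)}")
    n = len(records)
    props = {
        cls: sum(r.terminal_class is cls for r in records) / n
        for cls in TerminalClass
    }
    freqs = np.array([r.terminal_frequency for r in records])
    sd = float(freqs.std(ddof=1)) if n > 1 else 0.0
    return ReplicateSummary(
        scenario_id=records[0].scenario_id,
        n_replicates=n,
        proportions=props,
        mean_terminal_frequency=float(freqs.mean()),
        sd_terminal_frequency=sd,
    )
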