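"""Phenotype-census frequencies for a mutagenized population.

M2 lines with a visible phenotype (dwarfism, altered spike morphology,
albinism, ...) are tallied per category against the surveyed population;
a line with several altered traits is counted once, under its major
trait, so categories are disjoint and frequencies add.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence


@dataclass(frozen=True)
class PhenotypeTally:
    """Observed mutant count in one phenotype category."""

    category: str
    count: int
    population: int

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ValueError("population must be >= 1")
        if not 0 <= self.count <= self.population:
            raise ValueError("count must lie in [0, population]")


def category_frequency(tally: PhenotypeTally) -> float:
    """Percent frequency of one category, rounded half-up to 2 decimals."""
    pct = Decimal(100 * tally.count) / Decimal(tally.population)
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def overall_visible_rate(tallies: Sequence[PhenotypeTally]) -> float:
    """Percent of the population with any visible phenotype (unrounded).

    Categories must be disjoint (each mutant counted once) and share the
    same surveyed population size.
    """
    if not tallies:
        return 0.0
    populations = {t.population for t in tallies}
    if len(populations) != 1:
        raise ValueError(f"inconsistent population sizes: {sorted(populations)}")
    population = populations.pop()
    return 100.0 * sum(t.count for t in tallies) / population
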