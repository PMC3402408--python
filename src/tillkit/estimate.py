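"""Mutation-density estimators for EMS TILLING populations.

Two complementary estimators are implemented:

* the band-based RAPD/ISJ estimator, where each wild-type PCR band of a
  short arbitrary primer exposes ``2 * primer_length`` bp of scannable
  primer-binding sequence per screened line, and every gained or lost
  band counts as one mutation event::

      bp_per_mutation = (2 L) * (B * N) / m

  with L the primer length, B the wild-type band count, N the number of
  screened M2 lines and m the number of mutant bands; and

* the amplicon (TILLING) estimator, where an amplicon of ``full_length``
  bp contributes ``full_length - 2 * end_trim`` bp of effective sequence
  per screened plant (the 100 bp at each end are unreadable on gels)::

      bp_per_mutation = effective_bp * n_plants / n_mutations

Reported "one mutation per X kb" intervals truncate (floor) the bp value
to whole kb; this is the convention the reference tables follow.

Because M1 lesions are heterozygous and segregate 1:2:1 in M2, a screen
of M2 plants under-counts the germ-line density: over ``s`` siblings per
line the expected number of discovered unique mutations per germ-line
lesion per screened plant is ``(1 - (1/4)**s) / s``.
:func:`germline_density` applies this Mendelian transmission correction
when the quantity of interest is the M1 germ-line density rather than
the observed per-plant density.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean
from typing import Sequence


@dataclass(frozen=True)
class DensityEstimate:
    """A bp-per-mutation estimate plus its floored whole-kb report form."""

    bp_per_mutation: float

    def __post_init__(self) -> None:
        if not self.bp_per_mutation > 0:
            raise ValueError("bp_per_mutation must be > 0")

    @property
    def kb_report(self) -> int:
        """The 'one mutation per X kb' integer, truncated (never rounded)."""
        return math.floor(self.bp_per_mutation / 1000)


@dataclass(frozen=True)
class PrimerSurvey:
    """One RAPD/ISJ primer's screen over a set of M2 lines."""

    primer_name: str
    primer_length: int
    bands_wt: int
    n_lines: int
    mutant_bands: int
    sequence: str | None = None
    reported_kb: int | None = None

    def __post_init__(self) -> None:
        if self.primer_length < 1:
            raise ValueError("primer_length must be >= 1")
        if self.bands_wt < 1:
            raise ValueError("bands_wt must be >= 1")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")
        if self.mutant_bands < 0:
            raise ValueError("mutant_bands must be >= 0")


@dataclass(frozen=True)
class AmpliconScreenResult:
    """Mutation yield of one amplicon screened over a set of M2 plants."""

    gene: str
    full_length: int
    end_trim: int
    n_plants: int
    n_mutations: float
    method: str | None = None
    reported_kb: int | None = None

    def __post_init__(self) -> None:
        if self.full_length <= 2 * self.end_trim:
            raise ValueError("full_length must exceed twice the end trim")
        if self.n_plants < 1:
            raise ValueError("n_plants must be >= 1")
        if self.n_mutations < 0:
            raise ValueError("n_mutations must be >= 0")

    @property
    def effective_bp(self) -> int:
        return self.full_length - 2 * self.end_trim


def rapd_density(survey: PrimerSurvey) -> DensityEstimate:
    """Band-based mutation density for a single RAPD/ISJ primer."""
    if survey.mutant_bands < 1:
        raise ValueError(
            f"primer {survey.primer_name}: no mutant bands observed; "
            "the density estimate is undefined"
        )
    bp = (
        (2 * survey.primer_length)
        * (survey.bands_wt * survey.n_lines)
        / survey.mutant_bands
    )
    return DensityEstimate(bp_per_mutation=bp)


def mean_primer_density(estimates: Sequence[DensityEstimate]) -> DensityEstimate:
    """Average the per-primer reported kb intervals (not pooled bands)."""
    if not estimates:
        raise ValueError("no estimates to average")
    mean_kb = fmean(e.kb_report for e in estimates)
    return DensityEstimate(bp_per_mutation=mean_kb * 1000)


def pooled_primer_density(surveys: Sequence[PrimerSurvey]) -> DensityEstimate:
    """Alternative aggregation pooling scanned bp and mutant bands."""
    total_m = sum(s.mutant_bands for s in surveys)
    if total_m < 1:
        raise ValueError("no mutant bands across surveys")
    total_bp = sum(2 * s.primer_length * s.bands_wt * s.n_lines for s in surveys)
    return DensityEstimate(bp_per_mutation=total_bp / total_m)


def tilling_density(result: AmpliconScreenResult) -> DensityEstimate:
    """Amplicon mutation density after end-trimming."""
    if result.n_mutations <= 0:
        raise ValueError(
            f"amplicon {result.gene}: no mutations observed; estimate undefined"
        )
    bp = result.effective_bp * result.n_plants / result.n_mutations
    return DensityEstimate(bp_per_mutation=bp)


def pooled_tilling_density(results: Sequence[AmpliconScreenResult]) -> DensityEstimate:
    """Pool effective scanned bp and mutation counts across amplicons."""
    if not results:
        raise ValueError("no amplicon results")
    total_mut = sum(r.n_mutations for r in results)
    if total_mut <= 0:
        raise ValueError("zero total mutations across amplicons")
    total_bp = sum(r.effective_bp * r.n_plants for r in results)
    return DensityEstimate(bp_per_mutation=total_bp / total_mut)


def transmission_discovery_factor(siblings_per_line: int) -> float:
    """Expected unique discoveries per germ-line lesion per screened plant.

    A heterozygous M1 lesion is inherited by an M2 sibling with
    probability 3/4; over ``s`` siblings the line yields at least one
    carrier with probability ``1 - (1/4)**s`` while contributing ``s``
    plants to the denominator.
    """
    s = siblings_per_line
    if s < 1:
        raise ValueError("siblings_per_line must be >= 1")
    return (1.0 - 0.25**s) / s


def germline_density(
    estimate: DensityEstimate, siblings_per_line: int
) -> DensityEstimate:
    """Correct an observed per-plant density to the M1 germ-line scale."""
    f = transmission_discovery_factor(siblings_per_line)
    return DensityEstimate(bp_per_mutation=estimate.bp_per_mutation * f)


def round_to_2sf(x: float) -> float:
    """Round a positive number to two significant figures."""
    if x <= 0:
        raise ValueError("value must be positive")
    return round(x, -int(math.floor(math.log10(x))) + 1)


def genome_mutation_load(genome_size: float, bp_per_mutation: float) -> float:
    """Expected genome-wide mutation count, reported to 2 significant figures.

    E.g. a 16,000 Mb hexaploid wheat genome at one mutation per 47 kb
    carries ~340,000 induced mutations per individual.
    """
    if genome_size <= 0 or bp_per_mutation <= 0:
        raise ValueError("genome_size and bp_per_mutation must be positive")
    return round_to_2sf(genome_size / bp_per_mutation)
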