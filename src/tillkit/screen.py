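"""Pooled heteroduplex mismatch-cleavage screening model.

Equal amounts of genomic DNA from up to eight M2 plants are pooled, the
target amplicon is PCR-amplified, denatured and re-annealed so that a
mutant strand paired with a wild-type strand forms a heteroduplex, and a
single-strand-specific nuclease (CEL I from celery juice extract) cleaves
at the mismatch.  A cleaved pool shows two gel bands whose sizes sum to
the full amplicon length; the 100 bp nearest each amplicon end are
unreadable on gels and are excluded from the effective region.  Positive
pools are deconvolved by re-testing each member singly, mixed with
wild-type DNA so homozygous mutants still form heteroduplexes.

Detection methods differ only in sensitivity (probability that a true
in-region heteroduplex is called); the defaults are the relative yields
of the three gel systems on the same amplicon: silver-stained
polyacrylamide 15/15, ethidium-bromide agarose 14/15, ethidium-bromide
polyacrylamide 11/15.  No false positives are modeled (every call in the
source screens was sequencing-confirmed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .estimate import AmpliconScreenResult
from .simulate import Genotype, Population


@dataclass(frozen=True)
class AmpliconSpec:
    """A screened PCR target: 0-based half-open coordinates on the reference."""

    name: str
    start: int
    end: int
    end_trim: int = 100

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("amplicon end must exceed start")
        if self.end_trim < 0:
            raise ValueError("end_trim must be >= 0")
        if self.full_length <= 2 * self.end_trim:
            raise ValueError("amplicon must be longer than twice the end trim")

    @property
    def full_length(self) -> int:
        return self.end - self.start

    @property
    def effective_start(self) -> int:
        return self.start + self.end_trim

    @property
    def effective_end(self) -> int:
        return self.end - self.end_trim

    def in_effective_region(self, site: int) -> bool:
        return self.effective_start <= site < self.effective_end

    def fragments(self, site: int) -> tuple[int, int]:
        """Cleavage fragment sizes for a mismatch at ``site``."""
        return site - self.start, self.end - site


@dataclass(frozen=True)
class Pool:
    """A DNA pool of distinct individuals (fourfold by default, max eight)."""

    id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.members) <= 8:
            raise ValueError("pool size must be in [1, 8]")
        if len(set(self.members)) != len(self.members):
            raise ValueError("pool members must be distinct")


@dataclass(frozen=True)
class DetectionMethod:
    name: str
    sensitivity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in [0, 1]")


#: Default gel systems, sensitivities from their relative yields on one amplicon.
DETECTION_METHODS: dict[str, DetectionMethod] = {
    "page_silver": DetectionMethod("page_silver", 1.0),
    "agarose_etbr": DetectionMethod("agarose_etbr", 14 / 15),
    "page_etbr": DetectionMethod("page_etbr", 11 / 15),
}


@dataclass(frozen=True)
class CleavageCall:
    """One resolved mismatch-cleavage signal."""

    pool_id: str
    amplicon: str
    fragment_a: int
    fragment_b: int
    individual: str
    line: str
    site: int
    ref: str
    alt: str
    zygosity: str


def make_pools(
    individual_ids: Sequence[str], pool_size: int, seed: int | np.random.Generator
) -> list[Pool]:
    """Randomly partition individuals into pools of ``pool_size``.

    Every individual lands in exactly one pool; the last pool may be
    smaller.  Deterministic under a fixed seed.
    """
    if len(individual_ids) == 0:
        raise ValueError("no individuals to pool")
    if not 1 <= pool_size <= 8:
        raise ValueError("pool_size must be in [1, 8]")
    if len(set(individual_ids)) != len(individual_ids):
        raise ValueError("individual ids must be distinct")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    order = rng.permutation(len(individual_ids))
    shuffled = [individual_ids[i] for i in order]
    pools = []
    for k, lo in enumerate(range(0, len(shuffled), pool_size)):
        pools.append(Pool(id=f"pool{k + 1:04d}", members=tuple(shuffled[lo : lo + pool_size])))
    return pools


def heteroduplex_present(
    pool: Pool, site: int, genotypes: Mapping[str, Genotype]
) -> bool:
    """True iff the pooled allele mixture contains both ref and alt.

    An all-hom_alt pool, like an all-hom_ref pool, re-anneals into
    perfect homoduplexes and yields no cleavable mismatch.
    """
    has_ref = False
    has_alt = False
    for member in pool.members:
        try:
            gt = genotypes[member]
        except KeyError:
            raise KeyError(
                f"missing genotype for pool member {member!r} at site {site}"
            ) from None
        has_ref = has_ref or gt.dosage < 2
        has_alt = has_alt or gt.dosage > 0
    return has_ref and has_alt


def screen_amplicon(
    population: Population,
    amplicon: AmpliconSpec,
    pools: Sequence[Pool],
    method: DetectionMethod,
    seed: int | np.random.Generator,
) -> list[CleavageCall]:
    """Screen one amplicon over pooled DNA and deconvolve positives.

    A truth mutation generates calls only if its site lies in the
    effective region, the pool mixture forms a heteroduplex, and a
    Bernoulli(sensitivity) draw succeeds.  Every carrier in a positive
    pool is then resolved singly (spiked with wild-type DNA, so
    homozygous mutants remain detectable).
    """
    if amplicon.start < 0 or amplicon.end > population.reference.length:
        raise ValueError(
            f"amplicon {amplicon.name} [{amplicon.start}, {amplicon.end}) lies "
            f"outside the reference of length {population.reference.length}"
        )
    if amplicon.effective_end <= amplicon.effective_start:
        raise ValueError(f"amplicon {amplicon.name} has an empty effective region")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool_of: dict[str, Pool] = {}
    for pool in pools:
        for member in pool.members:
            pool_of[member] = pool

    sites = sorted(
        {rec.site for rec in population.truth if amplicon.in_effective_region(rec.site)}
    )
    calls: list[CleavageCall] = []
    seen: set[tuple[str, int, str]] = set()
    for site in sites:
        carrier_pools: dict[str, Pool] = {}
        for indiv, _gt in population.carriers(site):
            pool = pool_of.get(indiv.id)
            if pool is not None:
                carrier_pools[pool.id] = pool
        for pool_id in sorted(carrier_pools):
            pool = carrier_pools[pool_id]
            genotypes = {m: population.genotype(m, site) for m in pool.members}
            if not heteroduplex_present(pool, site, genotypes):
                continue
            if rng.random() >= method.sensitivity:
                continue
            frag_a, frag_b = amplicon.fragments(site)
            for member in pool.members:
                gt = genotypes[member]
                if gt.dosage == 0 or (pool.id, site, member) in seen:
                    continue
                seen.add((pool.id, site, member))
                calls.append(
                    CleavageCall(
                        pool_id=pool.id,
                        amplicon=amplicon.name,
                        fragment_a=frag_a,
                        fragment_b=frag_b,
                        individual=member,
                        line=population.line_of(member),
                        site=site,
                        ref=gt.ref,
                        alt=gt.alt,
                        zygosity=gt.zygosity,
                    )
                )
    return calls


def tally_calls(
    calls: Sequence[CleavageCall],
    amplicons: Sequence[AmpliconSpec],
    n_plants: int,
) -> list[AmpliconScreenResult]:
    """Collapse calls to unique mutations per M2 line and count per amplicon.

    Sibling repeats (the same substitution seen in several individuals of
    one line) count once, matching how screened allele tables are scored;
    identical substitutions in different lines stay distinct.
    """
    unique: dict[str, set[tuple[str, int, str, str]]] = {a.name: set() for a in amplicons}
    for call in calls:
        if call.amplicon not in unique:
            raise ValueError(f"call references unknown amplicon {call.amplicon!r}")
        unique[call.amplicon].add((call.line, call.site, call.ref, call.alt))
    return [
        AmpliconScreenResult(
            gene=a.name,
            full_length=a.full_length,
            end_trim=a.end_trim,
            n_plants=n_plants,
            n_mutations=len(unique[a.name]),
        )
        for a in amplicons
    ]
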