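"""Forward simulation of an EMS-mutagenized wheat TILLING population.

EMS (ethyl methanesulfonate) alkylates guanine, so induced point
mutations are almost exclusively G:C -> A:T transitions.  The simulator
mutagenizes M1 germ cells (every lesion heterozygous), optionally splits
the M1 germ line across independent meristem sectors to model chimerism,
selfs each M1 plant and samples a small number of M2 siblings per line.
At every M1-heterozygous site the M2 genotype segregates
hom_alt : het : hom_ref = 1 : 2 : 1.

Coordinates are 0-based, half-open throughout the package; file writers
convert to 1-based at the boundary (see :mod:`tillkit.io`).

All randomness flows from a single top-level seed; per-plant and
per-stage streams are spawned deterministically from it, so an identical
:class:`SimConfig` reproduces a bit-identical :class:`Population`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

ALPHABET = frozenset("ACGT")

#: EMS canonical transition on the reference strand.
EMS_TRANSITIONS = {"G": "A", "C": "T"}

_PURINES = (ord("A"), ord("G"))
_PYRIMIDINES = (ord("C"), ord("T"))


class SpectrumError(ValueError):
    """Requested mutation spectrum is impossible on this reference."""


@dataclass(frozen=True)
class ReferenceSequence:
    """A wild-type target sequence (e.g. a 'Jinmai47' gene region)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("reference sequence must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(f"non-ACGT residues in reference: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def gc_fraction(self) -> float:
        gc = self.residues.count("G") + self.residues.count("C")
        return gc / len(self.residues)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a mutagenesis/breeding/pooling run.

    target_density is the expected number of induced (heterozygous) M1
    lesions per bp of genome; wheat EMS populations run on the order of
    one lesion per 20-60 kb.  pool_size up to eight mirrors the pooling
    depths resolvable on silver-stained polyacrylamide gels.
    context_bias_weight > 1 up-weights G:C sites in 5'-PuG-3' context
    (the reported EMS sequence preference); the genome-wide expectation
    is renormalized so the realized density stays at target_density.
    """

    seed: int = 0
    target_density: float = 1.0 / 45_000
    n_m1: int = 64
    sectors_per_m1: int = 1
    siblings_per_line: int = 2
    pool_size: int = 4
    context_bias_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.target_density < 0:
            raise ValueError("target_density must be >= 0")
        if not 1 <= self.pool_size <= 8:
            raise ValueError("pool_size must be in [1, 8]")
        if self.sectors_per_m1 < 1:
            raise ValueError("sectors_per_m1 must be >= 1")
        if self.siblings_per_line < 1:
            raise ValueError("siblings_per_line must be >= 1")
        if self.n_m1 < 1:
            raise ValueError("n_m1 must be >= 1")
        if self.context_bias_weight <= 0:
            raise ValueError("context_bias_weight must be > 0")


@dataclass(frozen=True)
class MutationRecord:
    """One induced substitution, observed on the reference strand."""

    site: int
    ref: str
    alt: str
    line: str | None = None
    individual: str | None = None
    zygosity: str | None = None
    sector: int | None = None

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.site, self.ref, self.alt)


@dataclass(frozen=True)
class Genotype:
    """Diploid genotype of one individual at one segregating site."""

    site: int
    ref: str
    alt: str
    alleles: tuple[str, str]

    @property
    def dosage(self) -> int:
        """Copies of the mutant allele (0, 1 or 2)."""
        return sum(a == self.alt for a in self.alleles)

    @property
    def zygosity(self) -> str:
        return ("hom_ref", "het", "hom_alt")[self.dosage]


@dataclass
class M2Individual:
    id: str
    line: str
    sector: int
    #: genotypes at the sites segregating in this individual's sector
    genotypes: dict[int, Genotype]


@dataclass
class M2Family:
    line_id: str
    m1_parent: str
    siblings: list[M2Individual]


@dataclass
class Population:
    """Simulated M2 families plus the ground-truth mutation set."""

    reference: ReferenceSequence
    lines: list[M2Family]
    truth: list[MutationRecord]

    _site_alleles: dict[int, tuple[str, str]] = field(init=False, repr=False)
    _carriers_by_site: dict[int, list[tuple[M2Individual, Genotype]]] = field(
        init=False, repr=False
    )
    _individual_by_id: dict[str, M2Individual] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._site_alleles = {rec.site: (rec.ref, rec.alt) for rec in self.truth}
        self._individual_by_id = {}
        self._carriers_by_site = {}
        for indiv in self.individuals():
            self._individual_by_id[indiv.id] = indiv
            for site, gt in indiv.genotypes.items():
                if site not in self._site_alleles:
                    raise ValueError(
                        f"genotype at site {site} has no matching truth record"
                    )
                if gt.dosage > 0:
                    self._carriers_by_site.setdefault(site, []).append((indiv, gt))

    def individuals(self) -> Iterator[M2Individual]:
        for fam in self.lines:
            yield from fam.siblings

    def individual_ids(self) -> list[str]:
        return [indiv.id for indiv in self.individuals()]

    def genotype(self, individual_id: str, site: int) -> Genotype:
        """Genotype of an individual at a truth site (hom_ref if absent)."""
        try:
            indiv = self._individual_by_id[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual {individual_id!r}") from None
        gt = indiv.genotypes.get(site)
        if gt is not None:
            return gt
        try:
            ref, alt = self._site_alleles[site]
        except KeyError:
            raise KeyError(f"site {site} is not a segregating site") from None
        return Genotype(site=site, ref=ref, alt=alt, alleles=(ref, ref))

    def carriers(self, site: int) -> list[tuple[M2Individual, Genotype]]:
        """Individuals carrying at least one mutant allele at ``site``."""
        return list(self._carriers_by_site.get(site, []))

    def line_of(self, individual_id: str) -> str:
        return self._individual_by_id[individual_id].line


def generate_reference(
    length: int,
    gc_fraction: float,
    seed: int | np.random.Generator,
    seq_id: str = "ref",
) -> ReferenceSequence:
    """Generate a random reference sequence with the requested GC content."""
    if length < 1:
        raise ValueError("reference length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    drawn = rng.choice(codes, size=length, p=p)
    return ReferenceSequence(id=seq_id, residues=drawn.tobytes().decode("ascii"))


def _pug_context(seq: np.ndarray, g_mask: np.ndarray, c_mask: np.ndarray) -> np.ndarray:
    """Boolean mask of G:C sites in 5'-PuG-3' context on either strand.

    A G at i is in context when the preceding reference base is a purine;
    a C at i corresponds to a G on the complementary strand whose 5'
    neighbour is the complement of the reference base at i+1, which is a
    purine exactly when that base is a pyrimidine.
    """
    n = seq.size
    ctx = np.zeros(n, dtype=bool)
    prev_pu = np.zeros(n, dtype=bool)
    prev_pu[1:] = (seq[:-1] == _PURINES[0]) | (seq[:-1] == _PURINES[1])
    next_py = np.zeros(n, dtype=bool)
    next_py[:-1] = (seq[1:] == _PYRIMIDINES[0]) | (seq[1:] == _PYRIMIDINES[1])
    ctx[g_mask] = prev_pu[g_mask]
    ctx[c_mask] |= next_py[c_mask]
    return ctx


def induce_ems_mutations(
    reference: ReferenceSequence,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[MutationRecord]:
    """Draw EMS lesions for one M1 germ-cell genome.

    Per-site hit probabilities at G:C sites are rescaled so the expected
    genome-wide count equals ``target_density * length`` regardless of GC
    content; with ``context_bias_weight != 1`` the eligible sites are
    reweighted and renormalized so that expectation is preserved.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if config.target_density == 0:
        return []
    seq = np.frombuffer(reference.residues.encode("ascii"), dtype=np.uint8)
    g_mask = seq == ord("G")
    c_mask = seq == ord("C")
    eligible = np.flatnonzero(g_mask | c_mask)
    if eligible.size == 0:
        raise SpectrumError(
            "reference contains no G:C sites; EMS transitions are impossible"
        )
    expected = config.target_density * len(reference)
    weights = np.ones(eligible.size)
    if config.context_bias_weight != 1.0:
        ctx = _pug_context(seq, g_mask, c_mask)[eligible]
        weights[ctx] = config.context_bias_weight
    probs = np.minimum(expected * weights / weights.sum(), 1.0)
    hits = eligible[rng.random(eligible.size) < probs]
    records = []
    for i in hits:
        ref_base = "G" if g_mask[i] else "C"
        records.append(
            MutationRecord(site=int(i), ref=ref_base, alt=EMS_TRANSITIONS[ref_base])
        )
    return records


def simulate_m1(
    reference: ReferenceSequence,
    config: SimConfig,
    seed_sequence: np.random.SeedSequence | None = None,
) -> list[list[list[MutationRecord]]]:
    """Mutagenize ``n_m1`` plants, each with independent meristem sectors.

    Returns one list per M1 plant, holding one lesion list per sector.
    """
    if seed_sequence is None:
        seed_sequence = np.random.SeedSequence(config.seed)
    streams = seed_sequence.spawn(config.n_m1 * config.sectors_per_m1)
    out: list[list[list[MutationRecord]]] = []
    k = 0
    for _ in range(config.n_m1):
        sectors = []
        for s in range(config.sectors_per_m1):
            rng = np.random.default_rng(streams[k])
            k += 1
            sectors.append(
                [replace(rec, sector=s) for rec in induce_ems_mutations(reference, config, rng)]
            )
        out.append(sectors)
    return out


def breed_to_m2(
    m1_mutations: Sequence[Sequence[Sequence[MutationRecord]]],
    config: SimConfig,
    seed: int | np.random.Generator,
    reference: ReferenceSequence,
) -> Population:
    """Self each M1 plant and sample M2 siblings.

    Each sibling descends from exactly one meristem sector of its M1
    parent; at each M1-heterozygous site of that sector the sibling
    genotype is drawn hom_alt : het : hom_ref = 1 : 2 : 1, and lesions of
    other sectors are absent from the sibling.
    """
    if len(m1_mutations) == 0:
        raise ValueError("no M1 plants supplied")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lines: list[M2Family] = []
    truth: list[MutationRecord] = []
    for i, sectors in enumerate(m1_mutations, start=1):
        if len(sectors) == 0:
            raise ValueError(f"M1 plant {i} has an empty sector list")
        line_id = f"p{i}"
        for s_idx, recs in enumerate(sectors):
            for rec in recs:
                truth.append(
                    replace(rec, line=line_id, sector=s_idx, zygosity="het")
                )
        siblings = []
        for j in range(1, config.siblings_per_line + 1):
            sector = int(rng.integers(len(sectors)))
            genotypes: dict[int, Genotype] = {}
            for rec in sectors[sector]:
                u = rng.random()
                if u < 0.25:
                    alleles = (rec.alt, rec.alt)
                elif u < 0.75:
                    alleles = (rec.ref, rec.alt)
                else:
                    alleles = (rec.ref, rec.ref)
                genotypes[rec.site] = Genotype(
                    site=rec.site, ref=rec.ref, alt=rec.alt, alleles=alleles
                )
            siblings.append(
                M2Individual(id=f"{line_id}-{j}", line=line_id, sector=sector, genotypes=genotypes)
            )
        lines.append(M2Family(line_id=line_id, m1_parent=f"M1-{i}", siblings=siblings))
    return Population(reference=reference, lines=lines, truth=truth)


def simulate_population(
    reference: ReferenceSequence, config: SimConfig
) -> Population:
    """Run mutagenesis and breeding end to end under one top-level seed."""
    root = np.random.SeedSequence(config.seed)
    m1_ss, breed_ss = root.spawn(2)
    m1 = simulate_m1(reference, config, seed_sequence=m1_ss)
    return breed_to_m2(m1, config, np.random.default_rng(breed_ss), reference)
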