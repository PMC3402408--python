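"""Characterization of induced mutations.

Covers transition typing (EMS yields G>A / C>T on the reference strand),
effect classification against a minimal exon gene model, line-scoped
deduplication of sibling repeats, and effect/zygosity censuses.

Effect classes are exhaustive and mutually exclusive: ``intron``,
``silent``, ``missense``, ``nonsense`` and ``splice_junction`` (within
2 bp of an exon boundary on the intron side, i.e. the canonical GT/AG
dinucleotides).  Severity scores from external predictors (PSSM, SIFT)
are carried as opaque annotations and never computed here.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .simulate import MutationRecord, ReferenceSequence

EFFECT_CLASSES = ("intron", "silent", "missense", "nonsense", "splice_junction")

#: width of the splice-junction window on the intron side of each boundary
SPLICE_WINDOW = 2

_NT_CHANGE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_AA_CHANGE = re.compile(r"^([A-Z*])(\d+)([A-Z*])$")


def classify_transition(ref: str, alt: str) -> str:
    """Type a substitution as ``C>T``, ``G>A`` or ``non_canonical``.

    Anything other than the two EMS-canonical transitions on the
    reference strand is flagged as unexpected under EMS mutagenesis.
    """
    if ref not in "ACGT" or alt not in "ACGT" or len(ref) != 1 or len(alt) != 1:
        raise ValueError(f"bases must be single characters in ACGT, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if (ref, alt) == ("C", "T"):
        return "C>T"
    if (ref, alt) == ("G", "A"):
        return "G>A"
    return "non_canonical"


@dataclass(frozen=True)
class GeneModel:
    """A minimal gene model: ordered disjoint exons on the reference.

    The modeled exons are treated as the coding sequence;
    ``coding_offset`` skips leading bases of the concatenated (stranded)
    CDS before codon 1, and ``residue_offset`` anchors protein residue
    numbering when the model covers an internal slice of a larger gene.
    ``region`` bounds the annotatable window (defaults to the exon span).
    """

    gene_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    region: tuple[int, int] | None = None
    coding_offset: int = 0
    residue_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if self.coding_offset < 0:
            raise ValueError("coding_offset must be >= 0")

    @property
    def span(self) -> tuple[int, int]:
        return self.region if self.region is not None else (
            self.exons[0][0],
            self.exons[-1][1],
        )

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def is_partial(self) -> bool:
        """True when the modeled CDS is not a whole number of codons."""
        return (self.cds_length - self.coding_offset) % 3 != 0


@dataclass(frozen=True)
class EffectCall:
    """Predicted consequence of a substitution."""

    effect: str
    protein_notation: str | None = None

    def __post_init__(self) -> None:
        if self.effect not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect!r}")
        if self.effect in ("intron", "splice_junction") and self.protein_notation:
            raise ValueError(f"{self.effect} calls carry no protein notation")


@dataclass(frozen=True)
class AnnotatedMutation:
    """A mutation record with its transition type, effect and annotations."""

    record: MutationRecord
    transition: str
    effect: EffectCall | None = None
    repeat: bool = False
    scores: tuple[tuple[str, float], ...] = ()

    @property
    def line(self) -> str:
        """M2 line id: the record's line, else the individual id stem."""
        if self.record.line:
            return self.record.line
        if self.record.individual:
            return self.record.individual.rsplit("-", 1)[0]
        raise ValueError("record carries neither line nor individual id")

    def score(self, name: str) -> float | None:
        return dict(self.scores).get(name)


def _cds_index(model: GeneModel, site: int) -> int | None:
    """Map a genomic site into the stranded CDS, or None if intronic."""
    offset = 0
    forward = None
    for start, end in model.exons:
        if start <= site < end:
            forward = offset + (site - start)
            break
        offset += end - start
    if forward is None:
        return None
    if model.strand == "-":
        return model.cds_length - 1 - forward
    return forward


def _is_splice_junction(model: GeneModel, site: int) -> bool:
    """Within SPLICE_WINDOW bp of an exon boundary, on the intron side.

    Only internal boundaries (those that abut an intron inside the model
    span) define junctions.
    """
    for i, (start, end) in enumerate(model.exons):
        if i > 0 and start - SPLICE_WINDOW <= site < start:
            return True
        if i < len(model.exons) - 1 and end <= site < end + SPLICE_WINDOW:
            return True
    return False


def classify_effect(
    mutation: MutationRecord, model: GeneModel, reference: ReferenceSequence
) -> EffectCall:
    """Classify a substitution against the gene model.

    Intronic sites within the splice window become ``splice_junction``;
    other intronic sites are ``intron``.  Exonic sites are translated
    before/after with the standard genetic code; protein notation uses
    1-based residue numbering from the model's frame anchor (e.g.
    ``T438M``, ``S242S``, ``W10*``).
    """
    lo, hi = model.span
    if not lo <= mutation.site < hi:
        raise ValueError(
            f"site {mutation.site} outside modeled region [{lo}, {hi}) of "
            f"{model.gene_id}"
        )
    if reference.residues[mutation.site] != mutation.ref:
        raise ValueError(
            f"reference base {reference.residues[mutation.site]!r} at site "
            f"{mutation.site} does not match record ref {mutation.ref!r}"
        )
    cds_idx = _cds_index(model, mutation.site)
    if cds_idx is None:
        if _is_splice_junction(model, mutation.site):
            return EffectCall(effect="splice_junction")
        return EffectCall(effect="intron")

    cds = "".join(reference.residues[s:e] for s, e in model.exons)
    ref_base, alt_base = mutation.ref, mutation.alt
    if model.strand == "-":
        cds = str(Seq(cds).reverse_complement())
        ref_base = str(Seq(ref_base).complement())
        alt_base = str(Seq(alt_base).complement())
    assert cds[cds_idx] == ref_base

    rel = cds_idx - model.coding_offset
    if rel < 0:
        raise ValueError(
            f"site {mutation.site} falls before the frame anchor of {model.gene_id}"
        )
    codon_start = model.coding_offset + (rel // 3) * 3
    if codon_start + 3 > len(cds):
        raise ValueError(
            f"site {mutation.site} falls in a partial trailing codon of {model.gene_id}"
        )
    codon = cds[codon_start : codon_start + 3]
    within = cds_idx - codon_start
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(alt_codon).translate())
    residue = rel // 3 + 1 + model.residue_offset
    notation = f"{aa_ref}{residue}{aa_alt}"
    if aa_alt == aa_ref:
        return EffectCall(effect="silent", protein_notation=notation)
    if aa_alt == "*":
        return EffectCall(effect="nonsense", protein_notation=notation)
    return EffectCall(effect="missense", protein_notation=notation)


def annotate_mutation(
    record: MutationRecord,
    model: GeneModel | None = None,
    reference: ReferenceSequence | None = None,
    scores: Mapping[str, float] | None = None,
) -> AnnotatedMutation:
    """Build an :class:`AnnotatedMutation`, classifying the effect if a model is given."""
    effect = None
    if model is not None:
        if reference is None:
            raise ValueError("effect classification requires the reference sequence")
        effect = classify_effect(record, model, reference)
    return AnnotatedMutation(
        record=record,
        transition=classify_transition(record.ref, record.alt),
        effect=effect,
        scores=tuple(sorted((scores or {}).items())),
    )


def dedupe_sibling_repeats(
    records: Sequence[AnnotatedMutation],
) -> tuple[list[AnnotatedMutation], list[list[AnnotatedMutation]]]:
    """Collapse identical substitutions within one M2 line.

    Records sharing (line, site, ref, alt) are sibling repeats of one
    induced mutation and collapse to the first-seen record (with its
    ``repeat`` flag set); the same substitution in different lines stays
    distinct.  Returns the unique mutations in first-appearance order and
    the groups (size >= 2) that were collapsed.
    """
    groups: dict[tuple[str, int, str, str], list[AnnotatedMutation]] = {}
    order: list[tuple[str, int, str, str]] = []
    for ann in records:
        key = (ann.line, ann.record.site, ann.record.ref, ann.record.alt)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(ann)
    unique = [
        replace(groups[key][0], repeat=len(groups[key]) > 1) for key in order
    ]
    repeat_groups = [groups[key] for key in order if len(groups[key]) > 1]
    return unique, repeat_groups


def summarize_effects(records: Sequence[AnnotatedMutation]) -> dict:
    """Census of effect classes, transition types and zygosity.

    Zygosity counts follow the record's carrier genotype: ``het`` for
    heterozygotes, ``hom`` for homozygous mutants.
    """
    effects = Counter({cls: 0 for cls in EFFECT_CLASSES})
    transitions: Counter[str] = Counter()
    zygosity = Counter({"het": 0, "hom": 0})
    for ann in records:
        if ann.effect is not None:
            effects[ann.effect.effect] += 1
        transitions[ann.transition] += 1
        if ann.record.zygosity == "het":
            zygosity["het"] += 1
        elif ann.record.zygosity in ("hom", "hom_alt"):
            zygosity["hom"] += 1
    return {
        "effects": dict(effects),
        "transitions": dict(transitions),
        "zygosity": dict(zygosity),
    }


def parse_nucleotide_change(text: str) -> tuple[int, str, str]:
    """Parse ``C1687T``-style notation into (0-based site, ref, alt)."""
    m = _NT_CHANGE.match(text.strip())
    if not m:
        raise ValueError(f"malformed nucleotide change {text!r}")
    ref, pos, alt = m.groups()
    return int(pos) - 1, ref, alt


def effect_from_aa_change(text: str) -> EffectCall:
    """Interpret an amino-acid-change annotation (``S242S``, ``Intron``...)."""
    text = text.strip()
    if text.lower() == "intron":
        return EffectCall(effect="intron")
    if text.lower() in ("splice", "splice_junction", "splice junction"):
        return EffectCall(effect="splice_junction")
    m = _AA_CHANGE.match(text)
    if not m:
        raise ValueError(f"malformed amino-acid change {text!r}")
    aa_ref, _pos, aa_alt = m.groups()
    if aa_ref == aa_alt:
        return EffectCall(effect="silent", protein_notation=text)
    if aa_alt == "*":
        return EffectCall(effect="nonsense", protein_notation=text)
    return EffectCall(effect="missense", protein_notation=text)
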