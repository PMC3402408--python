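"""Readers, writers and bundled tables.

Internal coordinates are 0-based half-open; on-disk formats (FASTA
headers aside, mutation tables, GFF3) use 1-based positions and are
converted at this boundary.  TSV is the tabular interchange format
throughout (delimiter configurable where it matters).
"""

from __future__ import annotations

import hashlib
import json
import re
from importlib import resources
from pathlib import Path
from typing import NamedTuple, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import (
    AnnotatedMutation,
    annotate_mutation,
    effect_from_aa_change,
    parse_nucleotide_change,
    GeneModel,
)
from .census import PhenotypeTally
from .estimate import AmpliconScreenResult, PrimerSurvey
from .simulate import (
    Genotype,
    M2Family,
    M2Individual,
    MutationRecord,
    Population,
    ReferenceSequence,
)
from .screen import AmpliconSpec

_NON_ACGT = re.compile(r"[^ACGT]")

#: sha256 of the bundled tables, checked on load
_BUNDLED_SHA256 = {
    "rapd_primer_surveys.tsv": "df0c034bcd3a05b3264ff896d2e81440716b6a055bc8a7d36fa2e5859a80fde8",
    "tilling_amplicon_screens.tsv": "a38337ece6d7e3530b2bcd288671192fa6c9579c675149f46e30b6fd6a331b05",
    "ppd_d1_mutations.tsv": "eb15f86a2135c2989050d1030e6fc8d19a8b6579f714f1165bcad35bced40d5a",
    "phenotype_tallies.tsv": "dde6e72efff56598d236cb1d15f3d9d26d57f955112c3dcb7c4a4252824d0f40",
}


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Read reference sequences; uppercase, strict ACGT alphabet."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or malformed FASTA")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        m = _NON_ACGT.search(residues)
        if m:
            raise ValueError(
                f"{path}: record {rec.id!r} has non-ACGT character "
                f"{m.group()!r} at position {m.start() + 1}"
            )
        out.append(ReferenceSequence(id=rec.id, residues=residues))
    return out


def write_fasta(sequences: Sequence[ReferenceSequence], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in sequences
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Mutation / population tables

_TRUTH_COLUMNS = ["CHROM", "POS", "REF", "ALT", "LINE", "INDIV", "ZYGOSITY"]


def write_mutation_table(
    records: Sequence[MutationRecord], path: str | Path, chrom: str = "ref"
) -> None:
    """Write mutations as a VCF-like TSV (POS is 1-based on disk)."""
    rows = [
        {
            "CHROM": chrom,
            "POS": rec.site + 1,
            "REF": rec.ref,
            "ALT": rec.alt,
            "LINE": rec.line or ".",
            "INDIV": rec.individual or ".",
            "ZYGOSITY": rec.zygosity or ".",
        }
        for rec in records
    ]
    pd.DataFrame(rows, columns=_TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MutationRecord(
                site=int(row.POS) - 1,
                ref=row.REF,
                alt=row.ALT,
                line=None if row.LINE == "." else row.LINE,
                individual=None if row.INDIV == "." else row.INDIV,
                zygosity=None if row.ZYGOSITY == "." else row.ZYGOSITY,
            )
        )
    return out


def write_population(population: Population, out_dir: str | Path) -> None:
    """Serialize a population as reference.fasta + truth.tsv + TSV tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([population.reference], out / "reference.fasta")
    write_mutation_table(
        population.truth, out / "truth.tsv", chrom=population.reference.id
    )
    indiv_rows = []
    gt_rows = []
    for fam in population.lines:
        for sib in fam.siblings:
            indiv_rows.append(
                {"line": fam.line_id, "individual": sib.id, "sector": sib.sector}
            )
            for site, gt in sorted(sib.genotypes.items()):
                gt_rows.append(
                    {
                        "individual": sib.id,
                        "pos": site + 1,
                        "ref": gt.ref,
                        "alt": gt.alt,
                        "dosage": gt.dosage,
                    }
                )
    pd.DataFrame(indiv_rows, columns=["line", "individual", "sector"]).to_csv(
        out / "individuals.tsv", sep="\t", index=False
    )
    pd.DataFrame(gt_rows, columns=["individual", "pos", "ref", "alt", "dosage"]).to_csv(
        out / "genotypes.tsv", sep="\t", index=False
    )


def read_population(out_dir: str | Path) -> Population:
    out = Path(out_dir)
    reference = read_fasta(out / "reference.fasta")[0]
    truth = read_mutation_table(out / "truth.tsv")
    indiv_df = pd.read_csv(out / "individuals.tsv", sep="\t", dtype={"sector": int})
    gt_df = pd.read_csv(out / "genotypes.tsv", sep="\t")
    gts_by_indiv: dict[str, dict[int, Genotype]] = {}
    for row in gt_df.itertuples(index=False):
        site = int(row.pos) - 1
        dosage = int(row.dosage)
        alleles = {
            0: (row.ref, row.ref),
            1: (row.ref, row.alt),
            2: (row.alt, row.alt),
        }[dosage]
        gts_by_indiv.setdefault(row.individual, {})[site] = Genotype(
            site=site, ref=row.ref, alt=row.alt, alleles=alleles
        )
    families: dict[str, M2Family] = {}
    for row in indiv_df.itertuples(index=False):
        fam = families.setdefault(
            row.line, M2Family(line_id=row.line, m1_parent=f"M1-{row.line}", siblings=[])
        )
        fam.siblings.append(
            M2Individual(
                id=row.individual,
                line=row.line,
                sector=int(row.sector),
                genotypes=gts_by_indiv.get(row.individual, {}),
            )
        )
    return Population(reference=reference, lines=list(families.values()), truth=truth)


# ---------------------------------------------------------------------------
# Amplicons (BED-like) and gene models (GFF3 subset)

def read_amplicons(path: str | Path) -> list[AmpliconSpec]:
    """BED-like amplicon file: name, start, end (0-based half-open), end_trim."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "start", "end"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: amplicon file needs columns {sorted(required)}")
    out = []
    for row in df.itertuples(index=False):
        trim = int(getattr(row, "end_trim", 100))
        out.append(
            AmpliconSpec(name=row.name, start=int(row.start), end=int(row.end), end_trim=trim)
        )
    return out


def write_amplicons(amplicons: Sequence[AmpliconSpec], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"name": a.name, "start": a.start, "end": a.end, "end_trim": a.end_trim}
            for a in amplicons
        ]
    ).to_csv(path, sep="\t", index=False)


def read_gene_model(path: str | Path) -> GeneModel:
    """Parse a minimal GFF3 (gene + exon features, 1-based inclusive on disk)."""
    gene_id = None
    strand = None
    region = None
    exons: list[tuple[int, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            _seqid, _src, ftype, start, end, _score, fstrand, _phase, attrs = cols[:9]
            start0, end0 = int(start) - 1, int(end)
            if ftype == "gene":
                region = (start0, end0)
                strand = fstrand
                m = re.search(r"ID=([^;]+)", attrs)
                gene_id = m.group(1) if m else "gene"
            elif ftype in ("exon", "CDS"):
                exons.append((start0, end0))
                strand = strand or fstrand
    if not exons:
        raise ValueError(f"{path}: no exon/CDS features found")
    exons = sorted(set(exons))
    return GeneModel(
        gene_id=gene_id or "gene", strand=strand or "+", exons=tuple(exons), region=region
    )


# ---------------------------------------------------------------------------
# Bundled tables

class BundledTables(NamedTuple):
    primer_surveys: list[PrimerSurvey]
    amplicon_screens: list[AmpliconScreenResult]
    ppd_mutations: list[AnnotatedMutation]
    phenotype_tallies: list[PhenotypeTally]


def _bundled_path(name: str):
    return resources.files("tillkit.data").joinpath(name)


def _read_bundled(name: str) -> pd.DataFrame:
    path = _bundled_path(name)
    data = path.read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _BUNDLED_SHA256[name]:
        raise ValueError(f"bundled table {name} is corrupted (sha256 {digest})")
    return pd.read_csv(path.open("r"), sep="\t", dtype=str)


def parse_primer_surveys(df: pd.DataFrame) -> list[PrimerSurvey]:
    return [
        PrimerSurvey(
            primer_name=row.primer,
            primer_length=int(row.primer_length),
            bands_wt=int(row.bands_wt),
            n_lines=int(row.m2_screened),
            mutant_bands=int(row.mutant_bands),
            sequence=row.sequence,
            reported_kb=int(row.reported_kb),
        )
        for row in df.itertuples(index=False)
    ]


def parse_amplicon_screens(df: pd.DataFrame) -> list[AmpliconScreenResult]:
    return [
        AmpliconScreenResult(
            gene=row.gene,
            full_length=int(row.amplicon_bp),
            end_trim=int(row.end_trim_bp),
            n_plants=int(row.m2_screened),
            n_mutations=int(row.mutations_total),
            method=row.method,
            reported_kb=int(row.reported_kb),
        )
        for row in df.itertuples(index=False)
    ]


def parse_mutation_table(df: pd.DataFrame) -> list[AnnotatedMutation]:
    out = []
    for row in df.itertuples(index=False):
        site, ref, alt = parse_nucleotide_change(row.nucleotide_change)
        individual = row.individual
        line = individual.rsplit("-", 1)[0]
        zygosity = {"Het": "het", "Hom": "hom_alt"}[row.zygosity]
        scores = {}
        for name, value in (("PSSM", row.pssm), ("SIFT", row.sift)):
            if value not in (".", "", None):
                scores[name] = float(value)
        record = MutationRecord(
            site=site, ref=ref, alt=alt, line=line, individual=individual, zygosity=zygosity
        )
        ann = annotate_mutation(record, scores=scores)
        out.append(
            AnnotatedMutation(
                record=record,
                transition=ann.transition,
                effect=effect_from_aa_change(row.amino_acid_change),
                repeat=row.type == "repeat",
                scores=ann.scores,
            )
        )
    return out


def parse_phenotype_tallies(df: pd.DataFrame) -> list[PhenotypeTally]:
    return [
        PhenotypeTally(
            category=row.category,
            count=int(row.mutants_observed),
            population=int(row.population),
        )
        for row in df.itertuples(index=False)
    ]


def load_bundled_tables() -> BundledTables:
    """Load the packaged Jinmai47 wheat TILLING survey tables.

    Returns the six RAPD/ISJ primer surveys, the five amplicon screen
    rows, the 18 Ppd-D1 mutation records (three sibling-repeat pairs) and
    the 20 phenotype tallies.  Checksums are verified on read.
    """
    return BundledTables(
        primer_surveys=parse_primer_surveys(_read_bundled("rapd_primer_surveys.tsv")),
        amplicon_screens=parse_amplicon_screens(
            _read_bundled("tilling_amplicon_screens.tsv")
        ),
        ppd_mutations=parse_mutation_table(_read_bundled("ppd_d1_mutations.tsv")),
        phenotype_tallies=parse_phenotype_tallies(_read_bundled("phenotype_tallies.tsv")),
    )


# ---------------------------------------------------------------------------
# Config / reports

def read_run_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg


def write_report(report: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_of(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
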