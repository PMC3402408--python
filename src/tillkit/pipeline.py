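"""End-to-end simulate -> screen -> estimate -> annotate -> census runs.

The pipeline exists so the whole screening model can be exercised (and
its report reproduced bit-exactly) from one seeded configuration, with
each stage failure reported under its stage name.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np

from . import __version__
from .annotate import GeneModel, annotate_mutation, summarize_effects
from .census import category_frequency, overall_visible_rate
from .estimate import (
    genome_mutation_load,
    germline_density,
    pooled_tilling_density,
)
from .io import load_bundled_tables, sha256_of, write_population, write_report
from .screen import (
    AmpliconSpec,
    DETECTION_METHODS,
    make_pools,
    screen_amplicon,
    tally_calls,
)
from .simulate import SimConfig, generate_reference, simulate_population

logger = logging.getLogger("tillkit")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a demonstration pipeline run.

    Defaults give a desk-scale run: a 50 kb reference at one lesion per
    45 kb, 64 M1 lines x 2 siblings = 128 screened plants in fourfold
    pools, ten 1.5 kb amplicons with 100 bp dead zones.
    """

    seed: int = 1
    reference_length: int = 50_000
    gc_fraction: float = 0.46
    target_density: float = 1.0 / 45_000
    n_m1: int = 64
    sectors_per_m1: int = 1
    siblings_per_line: int = 2
    pool_size: int = 4
    method: str = "page_silver"
    n_amplicons: int = 10
    amplicon_length: int = 1500
    end_trim: int = 100
    genome_size_bp: float = 1.6e10
    out_dir: str | None = None

    def sim_config(self, seed: int) -> SimConfig:
        return SimConfig(
            seed=seed,
            target_density=self.target_density,
            n_m1=self.n_m1,
            sectors_per_m1=self.sectors_per_m1,
            siblings_per_line=self.siblings_per_line,
            pool_size=self.pool_size,
        )


def tile_amplicons(config: RunConfig) -> list[AmpliconSpec]:
    """Evenly tile non-overlapping amplicons over the reference."""
    spacing = config.reference_length // config.n_amplicons
    if config.amplicon_length > spacing:
        raise ValueError("amplicons would overlap; reduce n_amplicons or length")
    return [
        AmpliconSpec(
            name=f"amp{i + 1:02d}",
            start=i * spacing,
            end=i * spacing + config.amplicon_length,
            end_trim=config.end_trim,
        )
        for i in range(config.n_amplicons)
    ]


def _demo_gene_model(amplicon: AmpliconSpec) -> GeneModel:
    """A three-exon model inside the first amplicon's effective region."""
    lo = amplicon.effective_start
    exon_len, intron_len = 150, 120
    exons = []
    pos = lo
    for _ in range(3):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return GeneModel(
        gene_id=f"{amplicon.name}_gene",
        strand="+",
        exons=tuple(exons),
        region=(amplicon.start, amplicon.end),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return a machine-readable report.

    Rerunning with an identical config reproduces the report bit-exactly.
    """
    root = np.random.SeedSequence(config.seed)
    sim_seed, pool_ss, screen_ss = root.spawn(3)

    stage = "simulate"
    try:
        reference = generate_reference(
            config.reference_length,
            config.gc_fraction,
            np.random.default_rng(sim_seed),
            seq_id="simref",
        )
        sim_config = config.sim_config(seed=config.seed)
        population = simulate_population(reference, sim_config)
        logger.info(
            "simulate: %d truth mutations across %d lines",
            len(population.truth),
            len(population.lines),
        )
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise StageError(stage, exc) from exc

    stage = "screen"
    try:
        if config.method not in DETECTION_METHODS:
            raise ValueError(f"unknown detection method {config.method!r}")
        method = DETECTION_METHODS[config.method]
        amplicons = tile_amplicons(config)
        pools = make_pools(
            population.individual_ids(),
            config.pool_size,
            np.random.default_rng(pool_ss),
        )
        screen_rng = np.random.default_rng(screen_ss)
        calls = []
        for amplicon in amplicons:
            calls.extend(
                screen_amplicon(population, amplicon, pools, method, screen_rng)
            )
        logger.info("screen: %d cleavage calls from %d pools", len(calls), len(pools))
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "estimate"
    try:
        n_plants = len(population.individual_ids())
        results = tally_calls(calls, amplicons, n_plants)
        pooled = pooled_tilling_density(results)
        corrected = germline_density(pooled, config.siblings_per_line)
        load = genome_mutation_load(config.genome_size_bp, corrected.bp_per_mutation)
        per_amplicon = {
            r.gene: (
                None
                if r.n_mutations == 0
                else {"bp_per_mutation": r.effective_bp * r.n_plants / r.n_mutations}
            )
            for r in results
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "annotate"
    try:
        model = _demo_gene_model(amplicons[0])
        annotated = [
            annotate_mutation(rec, model=model, reference=reference)
            for rec in population.truth
            if model.span[0] <= rec.site < model.span[1]
        ]
        effect_summary = summarize_effects(annotated)
        transitions = summarize_effects(
            [annotate_mutation(rec) for rec in population.truth]
        )["transitions"]
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    stage = "census"
    try:
        tallies = load_bundled_tables().phenotype_tallies
        frequencies = {t.category: category_frequency(t) for t in tallies}
        visible_rate = overall_visible_rate(tallies)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in asdict(config).items() if k != "out_dir"},
        "simulate": {
            "n_truth_mutations": len(population.truth),
            "n_lines": len(population.lines),
            "n_individuals": n_plants,
            "reference_gc": round(reference.gc_fraction, 4),
        },
        "screen": {
            "method": config.method,
            "n_pools": len(pools),
            "n_calls": len(calls),
        },
        "estimate": {
            "per_amplicon": per_amplicon,
            "pooled_bp_per_mutation": pooled.bp_per_mutation,
            "pooled_kb_report": pooled.kb_report,
            "germline_bp_per_mutation": corrected.bp_per_mutation,
            "germline_kb_report": corrected.kb_report,
            "genome_mutation_load": load,
        },
        "annotate": {
            "demo_gene_effects": effect_summary["effects"],
            "truth_transitions": transitions,
        },
        "census": {
            "frequencies_pct": frequencies,
            "overall_visible_rate_pct": visible_rate,
        },
    }

    if config.out_dir is not None:
        from pathlib import Path

        out = Path(config.out_dir)
        write_population(population, out / "population")
        report["inputs_sha256"] = {
            "reference.fasta": sha256_of(out / "population" / "reference.fasta")
        }
        write_report(report, out / "report.json")
    return report
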