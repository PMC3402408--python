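# Methods

## The system being modeled

An EMS-mutagenized TILLING population of hexaploid bread wheat
(cv. Jinmai47): ~3,000 seeds soaked in 0.8% EMS, 1,350 M1 plants grown
to maturity, and 2,610 M2 individuals (two to three siblings per M1
line) phenotyped and screened molecularly. Mutation density is estimated
two ways — genome-wide from RAPD/ISJ banding-pattern changes over 300
lines, and locus-specific from pooled mismatch-cleavage (CEL I) screens
of three gene amplicons over 512 plants — and the locus density is
extrapolated to a genome-wide mutation load.

## Forward simulator

**Mutagenesis.** EMS alkylates guanine, so lesions are modeled strictly
as G→A or C→T on the reference strand (the complementary-strand event is
not tracked separately; this matches the `C1687T`-style notation of
allele tables). Per-site hit probabilities at G:C sites are rescaled so
the expected genome-wide count equals `target_density × length`
independent of GC content. An optional `context_bias_weight` up-weights
G:C sites in 5′-PuG-3′ context (on either strand) and renormalizes, so
the sequence preference can be switched on without changing the realized
density; the default is 1.0 (off) because the preference is reported
only qualitatively, with no published magnitude.

**Breeding.** Every M1 lesion is heterozygous in the M1 germ line (EMS
alkylates a single strand; observed M2 segregation implies M1
heterozygosity). An M1 plant consists of `sectors_per_m1` independent
meristem sectors, each mutagenized independently; each sampled M2
sibling descends from exactly one sector, so siblings from different
sectors carry disjoint mutation sets (chimerism). The default is one
sector — chimerism was observed once in the source screens — but the
parameter exists because the phenomenon is real. At each
M1-heterozygous site the sibling genotype is drawn
hom_alt : het : hom_ref = 1 : 2 : 1.

**Determinism.** One top-level seed; all per-plant and per-stage streams
are spawned from it via `numpy.random.SeedSequence`, so an identical
`SimConfig` reproduces a bit-identical population.

**Defaults** mirror the study conditions: `target_density` 1/45 kb
(within the 1/20–1/60 kb range wheat EMS populations exhibit),
`siblings_per_line` 2, `pool_size` 4 (eightfold allowed — the resolution
limit of silver-stained gels), `sectors_per_m1` 1.

## Screening model

An amplicon is a coordinate window with a 100 bp `end_trim` dead zone at
each end ("base ambiguity" near primers); only the effective region is
scorable. A truth mutation produces a pool signal iff (i) its site lies
in the effective region, (ii) the pool's allele mixture contains both
ref and alt alleles (an all-homozygous-mutant pool forms no
heteroduplex), and (iii) a Bernoulli(sensitivity) draw succeeds.
Fragment sizes are reported amplicon-relative as `(site − start,
end − site)` and always sum to the full length. Positive pools are
deconvolved by re-testing each member singly, mixed with wild-type DNA,
so homozygous mutants remain detectable; every carrier in a positive
pool yields a resolved call. No false positives are modeled (all
reported calls were sequencing-confirmed), so specificity is fixed at 1.
Two mutations in one amplicon and pool are treated as independently
detectable; band co-migration is not modeled.

**Sensitivities.** The three gel systems are distinguished only by
sensitivity, calibrated from their relative yields on the same amplicon
screened in the same plants: silver-stained polyacrylamide 15/15 = 1.00,
ethidium-bromide agarose 14/15 ≈ 0.93, ethidium-bromide polyacrylamide
11/15 ≈ 0.73. These are configurable; they are relative detection rates,
not physical measurements.

## Estimators

**Band-based (RAPD/ISJ).** Each wild-type band exposes two
primer-binding sites of `primer_length` bp per screened line, so a
primer scans `2L·B·N` bp across the survey and
`bp_per_mutation = 2L·B·N / m`. Gained and lost bands are counted
identically, and `m` is a plain event count (one line may contribute
several mutant bands). The survey-wide summary averages the per-primer
*reported kb intervals* (mean of 36, 16, 10, 86, 31, 27 → 34.33 → 34 kb);
pooling scanned bp over all primers instead gives 25 kb and is provided
as `pooled_primer_density` for comparison, but the per-primer mean is
the default because it is the reported convention.

**Amplicon (TILLING).** `bp_per_mutation = (full_length − 2·end_trim) ×
n_plants / n_mutations`, with mutation counts deduplicated per M2 line
(a substitution seen in two siblings of one line is one induced
mutation). The multi-amplicon aggregation pools effective bp and counts:
`Σ(effective_bp × n_plants) / Σ n_mutations`.

**kb reporting truncates.** `kb_report = floor(bp_per_mutation / 1000)`.
Truncation, not rounding, reproduces all eleven printed "1/X kb" values
(10500 → 10, 31500 → 31, 54565 → 54); half-up rounding would fail three
of them.

**Mendelian transmission correction.** The raw amplicon estimator
measures mutations *discovered per screened M2 plant*. A heterozygous M1
lesion is carried by an M2 sibling with probability 3/4, and over `s`
screened siblings per line the lesion is discovered (in at least one
sibling, counted once) with probability `1 − (1/4)^s`, while the line
contributes `s` plants to the denominator. The expected discovery factor
is therefore `f(s) = (1 − (1/4)^s)/s` — 0.75 at s = 1, 15/32 ≈ 0.469 at
s = 2 — and the M1 germ-line density is the observed density divided by
`f(s)` (equivalently, `bp_per_mutation × f(s)`). `germline_density`
applies this correction; the raw estimator is retained unchanged for
reproducing published per-plant figures, which do not apply it. The
simulation-based recovery check (512 plants, two siblings per line,
twelve amplicons totaling > 20 kb effective sequence at sensitivity 1.0)
uses the corrected estimate and recovers a target density of 1/47 kb
with ~0.2% bias averaged over 20 seeds.

**Load extrapolation.** `genome_mutation_load = genome_size /
bp_per_mutation`, reported to two significant figures (16,000 Mb at
1/47 kb → 340,000).

## Annotation

Transitions are typed C>T / G>A / non_canonical (the latter flagged as
unexpected under EMS). Effect classification uses a minimal exon model:
intronic sites within 2 bp of an exon boundary on the intron side (the
canonical GT/AG dinucleotides) are `splice_junction`; other intronic
sites are `intron`; exonic sites are translated before/after with the
standard nuclear genetic code (Biopython) — same residue → `silent`,
stop gained → `nonsense`, otherwise `missense`, with `X<pos>Y` notation
numbered from the model's frame anchor. Deduplication is scoped to the
M2 line: identical (site, ref, alt) within one line collapse to one
unique mutation; across lines they stay distinct. The bundled *Ppd-D1*
allele table's effect labels are consumed as given when tallying (its
residue numbering derives from the full GenBank CDS, which is out of
scope); classification is recomputed only when a gene model is supplied.
PSSM/SIFT severity scores are opaque pass-through annotations (the
source's damage thresholds were PSSM > 10, SIFT < 0.05); they are never
computed here.

## Census

Category frequencies are `100 × count / population`, rounded half-up to
two decimals (reproduces all 20 printed percentages, e.g. 8/2610 =
0.3065 → 0.31). The overall visible-phenotype rate sums disjoint
categories (a line with several altered traits is tallied once under its
major trait): 108/2610 = 4.14%, consistent with the reported "about 4%";
a separately quoted figure of 3.8% has no stated basis and is not
reproduced — the operation reports the computed sum only.

## Coordinates and I/O

Internal coordinates are 0-based half-open everywhere. On-disk mutation
tables and GFF3 are 1-based (inclusive for GFF3) and converted at the
I/O boundary; FASTA is read strictly (uppercase, ACGT only, offending
position reported). Bundled tables are TSV with sha256 verification.
Pipeline reports include the package version, seed and reference
checksum and are bit-reproducible under a fixed config.

## What the synthetic data does and does not capture

The generator reproduces the *statistical* structure relevant to the
estimators: EMS spectrum and density, M1 chimerism, Mendelian M2
segregation, sibling sampling, pooling, dead zones and sensitivity. It
does not model PCR at the nucleotide level (amplicons are coordinate
windows), enzyme kinetics, band intensity or co-migration, dose–response
of germination, homoeologous-copy cross-amplification, or real genomic
sequence composition beyond GC content. Passing recovery tests therefore
demonstrate estimator correctness under the stated sampling model, not
robustness to those unmodeled effects.

## Numerical and design choices

- Reported kb values floor; means over primer estimates are taken on the
  floored kb scale (the reported convention).
- Sensitivity draws occur once per (site, pool) positive-candidate
  event, making call counts monotone in sensitivity under a fixed seed.
- Degenerate inputs fail loudly: zero mutant bands / zero mutations give
  undefined-estimate errors rather than infinities; amplicons shorter
  than twice the end trim, references without G:C sites (impossible
  spectrum), pools over eight members, and inconsistent census
  population sizes are all rejected.
- Demonstration problem sizes (50 kb reference, 128 plants for the
  pipeline; 30 kb × 512 plants × 20 seeds for recovery checks) were
  chosen so the full analysis reruns in seconds while keeping counting
  error a few percent.

## Known limitations

- The band-based estimator ignores mutations outside primer-binding
  regions and 5′-end binding-site insensitivity; it underestimates
  density, as acknowledged qualitatively by its users.
- No confidence intervals are attached to density estimates (none are
  published for comparison); counts are small enough that seed-to-seed
  spread of a single pooled estimate is ±15%.
- The transmission correction assumes independent 1:2:1 segregation and
  complete deconvolution; selection against deleterious lesions, seed
  sampling with replacement across tillers, and pooling-induced
  detection interactions are not modeled.
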