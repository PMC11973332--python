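# recruitplot

Recruitment-plot taxonomic profiling for short- and long-read metagenomes,
with a DNA-fragmentation intactness model and a ground-truthed synthetic
community simulator.

The package implements the decision rules of recruitment-plot profiling
against a custom multi-genome reference — host-read removal, identity and
overlap filters, best-hit selection with seeded random tie-breaking,
read-count and spread-based species retention, coverage-gap fingerprints,
and subspecies read-count ratios — plus read-count and base-weighted
relative-abundance tables, a minimum-read-length threshold sweep, and the
intact-target model

```
I(S, L) = (S − L + 1) / S   if S ≥ L,   else 0
```

which links species-specific DNA fragment size `S` to the fraction of
length-`L` amplicon targets (e.g. 300 bp V4 vs 1,500 bp full-length 16S)
that survive intact. A synthetic community generator produces reference
genomes (with subspecies variants), species-specific lognormal
fragmentation, shotgun short reads, long reads, amplicon counts, and full
per-read provenance, so every pipeline stage can be tested against ground
truth without downloads.

## Package layout

| Module | Contents |
| --- | --- |
| `recruitplot.alignment_io` | `AlignmentHit`, `ReferenceDB`, blast6/PAF readers + blast6 writer, FASTA/FASTQ helpers, `toy_align` (built-in ungapped seed-and-extend aligner) |
| `recruitplot.recruitment` | `FilterConfig`, host removal, platform filters, best-hit tie-breaking, `RecruitmentProfile` building, species retention, gap detection/concordance, subspecies ratios, genus selection |
| `recruitplot.abundance` | `AbundanceTable`, read-count and base-weighted abundances, length sweep, read-length densities/N50, minority pooling, closest-threshold search, paired method-comparison statistics |
| `recruitplot.fragmentation` | `intact_fraction`, amplicon bias ratio, closed-form inverse, copy-number-aware amplicon prediction |
| `recruitplot.simulate` | `SimulationConfig`, reference/reads/amplicon simulators, `count_intact_targets` Monte-Carlo oracle, truth-based oracle alignments |
| `recruitplot.cli` | `run_pipeline` orchestration, plot-data export, click CLI |

## CLI

```bash
# generate a seeded synthetic bundle (genomes, reads, truth tables)
recruitplot simulate --seed 1 --out-dir sim/

# align reads with the built-in toy aligner (or substitute real blastn
# outfmt-6 / PAF output at this boundary)
recruitplot align --reads sim/reads_short.fastq --reference sim/genomes.fasta \
    --metadata sim/metadata.tsv --out sim/hits.tsv

# full pipeline: host removal -> filters -> best hit -> retention ->
# abundance (+ sweep for long reads), all report tables + manifest
recruitplot report --alignments sim/hits.tsv --metadata sim/metadata.tsv \
    --platform short --out-dir results/

# intactness model
recruitplot model -S 1000 -L 1500
```

Subcommands: `simulate`, `align`, `recruit`, `abundance`, `sweep`,
`model`, `report`. Exit codes: 0 ok, 2 configuration error, 3 data error.
`--config FILE` accepts a flat `key = value` file mirroring the flags.

### Output schema

`report` writes into `--out-dir`:

- `best_hits.tsv` — blast6 (12 columns + qlen) of the post-filter best hits
- `retention.tsv` — species, reads, breadth, best_genome, retained, reason
- `abundance.tsv` — sample_id, species, mode, min_read_length, fraction, percent
- `sweep.tsv` (long platform) — abundance rows per threshold + retained_bp_fraction
- `gaps.tsv` — genome_id, bin, covered (1-based bins over 100 genome windows)
- `ratios.tsv` — species, genome_a, genome_b, count_a, count_b, ratio
- `plot_data/<genome>.tsv` — position, percent_identity, read_length, read_id
- `manifest.json` — config, config hash, seed, per-stage read accounting

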