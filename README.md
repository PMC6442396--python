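# lrkit — a Linked-Read analysis toolkit

Linked-Read sequencing barcodes the short reads derived from each long
(tens-of-kb) DNA molecule: high molecular weight DNA is diluted into more than
a million droplet partitions, each partition carries one barcode from a
multi-million-entry whitelist, and every read pair records the barcode of its
partition in a `BX:Z:` tag.  Because a partition holds only a few molecules,
reads sharing a barcode almost always come from the same molecule, which turns
ordinary paired-end data into long-range information: multi-megabase haplotype
phasing, detection of balanced and unbalanced structural variants from barcode
sharing, and rescue of reads that multi-map between distant repeat copies.

`lrkit` implements that analysis stack end-to-end on simulated data, for
method developers and teaching: a diploid Linked-Read simulator with complete
truth tracking, and the algorithms that consume its output.

## What is inside

| module | what it does |
|---|---|
| `lrkit.simulate` / `lrkit.genome` | diploid genome with planted het SNVs, indels, and SVs (DEL/DUP/INV/TRA); barcoded molecules and read pairs with exact truth alignments |
| `lrkit.molecules` | molecule inference: single-linkage clustering of same-barcode reads (gap > 50 kb splits; ≥ 4 reads); length-weighted mean ΣL²/ΣL |
| `lrkit.rescue` | read-cloud rescue of multi-mapping reads: posterior ∝ exp(score)·[p_new + (1−p_new)·supported], MapQ = −10·log₁₀(1−posterior) |
| `lrkit.phasing` | pileup het genotyper; molecule cis/trans links with weight w = log₁₀((1−ε)/ε); parity union-find phase blocks + windowed exhaustive refinement |
| `lrkit.svcall` | barcode-overlap scan (hypergeometric + Benjamini–Hochberg), depth segmentation CNVs, haplotype-resolved deletion calls, segdup CANDIDATE filter |
| `lrkit.evaluate` | N50, short/long switch-error decomposition, gene finishing, coverage evenness, unique coverage gain, reciprocal-overlap SV benchmarking, heterozygosity |

Formats: FASTA, barcoded FASTQ, VCF 4.2 (phased `GT` + `PS`), BED, BEDPE, and
TSV tables for molecules and alignments.  A thin CLI (`lrk simulate`,
`lrk molecules`, `lrk phase`, `lrk svcall`, `lrk evaluate`) wraps the library.

## Worked example

`examples/` contains one short script per capability.  For instance:

```bash
python examples/03_phase_blocks.py
```

simulates a 2 × 2 Mb diploid genome (1 het SNV per kb, 50 kb molecules, ~30×)
and phases it:

```
het sites called   : 3900 (truth 3922)
phase blocks (>1)  : 2
phase block N50    : 1,999,301 bp
short switch rate  : 0.00e+00 per phased het
long switch rate   : 0.00e+00 per phased het
within-block corr. : 1.0000
```

At this heterozygosity nearly every adjacent pair of het sites is bridged by
several 50 kb molecules, so each chromosome collapses into a single phase
block spanning it end to end and no switch errors remain.  Lowering the het
rate or the molecule length breaks the chain — `examples/04`–`05` show the SV
callers and the multi-mapper rescue the same way.

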