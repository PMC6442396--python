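# Methods

This note documents the models and numerical choices behind `lrkit`: what the
simulator emulates, how each analysis stage works, which parameters matter,
and what the synthetic experiments do and do not demonstrate about real data.

## The Linked-Read data model

The simulator emulates a droplet-partitioned barcoded library. High molecular
weight DNA molecules are loaded into partitions (Poisson loading,
`molecules_per_partition_mean`); each occupied partition receives a distinct
16-mer barcode drawn from a whitelist (`barcode_whitelist_size`, default
4,000,000, with `n_partitions` default above one million mirroring the
platform regime); each molecule is sequenced shallowly by paired-end short
reads carrying the partition barcode. The key regime parameters:

* **Molecule length** — exponential with configurable mean (default 75 kb;
  the experiments here use 50 kb). Exponential matches random-fragmentation
  physics and is the simplest model whose moments are testable; a lognormal
  alternative (`molecule_length_model="lognormal"`) is provided for
  tighter-than-exponential length distributions. Molecules are sampled on an
  extended coordinate range and truncated at chromosome ends so expected
  physical coverage is uniform, including the edges.
* **Per-molecule read coverage** (`per_molecule_read_coverage`, default
  0.8×) — each molecule receives `round(c·L/(2·read_length))` read pairs
  placed uniformly with a Normal(385, 50) insert model. At 0.8× the expected
  gap between a molecule's end and its outermost read is
  `2·read_length/c ≈ 375 bp`, so inferred molecule boundaries are accurate to
  well under 1 kb; the physical molecule coverage at 30× read depth is then
  ~37×. Production platforms run shallower per molecule; 0.8× was chosen once
  so that molecule boundaries are identifiable at desk scale while preserving
  the defining property that single molecules are far below 1× coverage.
* **Diploid variation** — het SNVs at `het_snv_rate` (default 1e-3, one site
  per 1–2 kb as in human samples), short indels (1–10 bp), and heterozygous
  SVs (DEL, tandem DUP, INV, balanced reciprocal TRA) planted with 5 kb
  exclusion margins. Small variants are thinned to a 20 bp minimum spacing so
  edits never overlap. Each haplotype chromosome carries a block map back to
  reference coordinates (split at indels and SV junctions, orientation-aware
  for inversions), which is how reads get exact truth placements without an
  aligner.
* **Errors** — uniform substitution errors at `base_error_rate` (default
  1e-3) at distinct positions per read. No GC bias, no chimeric molecules,
  no barcode errors, no duplicates, and truth alignments are exact: passing
  tests demonstrate algorithmic correctness under the data model, not
  robustness to real-world alignment noise.

### Desk-scale study conditions

The reference experiments use a 10 Mb diploid genome (2 × 5 Mb) at ~30× read
depth. On a genome 300× smaller than human, keeping the platform's 3+
molecules per partition would inflate the probability that two molecules of
one partition land close enough to be merged by molecule inference (the
collision scale is molecule footprint / genome length). The desk-scale runs
therefore load one molecule per partition on average (7,500 partitions),
which reproduces the platform's low-collision regime; the allelic-collision
closed form `n_partitions·λ²·μ/(2G)` is verified by simulation in the test
suite, along with the property that collisions fall as partitions increase at
fixed molecule count.

## Molecule inference

Reads sharing a barcode on one chromosome are single-linkage clustered; a
start-to-previous-end gap above `gap_threshold` (default 50 kb) splits
clusters and clusters with fewer than `min_reads` (default 4) reads are
dropped; reads below MapQ 30 are excluded. The defaults reflect the two
scales in the data: intra-molecule read gaps at 0.8× coverage are a few
hundred bp (tens of kb only with vanishing probability), while distinct
same-barcode molecules land megabases apart on a human-scale genome.
Clustering is verified against an all-pairs single-linkage oracle on small
inputs, and is idempotent and monotone in the gap threshold.

The **length-weighted mean** ΣL²/ΣL is the standard molecule-length QC
metric (the expected length of the molecule under a random base); for
exponential lengths it is twice the plain mean. Inferred values sit slightly
below truth because the inferred interval `[first read, last read)`
undershoots each end by one expected gap.

## Barcode-aware rescue

A multi-mapping read is scored with a two-component mixture: with prior
`prior_new_molecule` (default 0.1) it comes from an unseen molecule (all
candidates equal a priori), otherwise it belongs to a molecule already
inferred for its barcode, so only candidates within `support_window` (50 kb,
the molecule scale) of a same-barcode molecule are plausible:

    posterior_j ∝ exp(score_j) · [p_new + (1 − p_new)·supported_j]

MapQ is recomputed as `min(cap, round(−10·log10(1 − posterior)))`. Two
consequences are asserted in tests: a score lead above `log(1/p_new)` can
never be overturned by support, and on a two-copy repeat genome with copies
far beyond the support window, rescue places ≥95% of repeat-internal reads at
their true copy when ≥3 confident same-barcode reads flank them, while a
barcode-blind argmax lands at ~50%. Molecules are inferred from confidently
mapped reads (MapQ ≥ 30) in a first pass only, so rescued reads never support
themselves. Per-read scoring against fixed molecules is a deliberate
simplification; a joint optimization over all reads of a barcode could
propagate rescue decisions but is out of scope.

## Genotyping and phasing

**Het calling** is a pileup: a site is heterozygous when depth ≥ 8 and both
the reference and one alternate allele are seen at ≥ `min_allele_frac` of
reads. The fraction floor is 0.15 rather than a binomial-style 0.25 because
Linked-Read depth is molecule-clustered: each haplotype's local depth comes
from a handful of molecules (compound-Poisson, overdispersed), so genuine het
sites regularly show 20–25% minor-allele fractions at 30×. At 0.15 a false
het still requires about five identical substitution errors at one site —
negligible at 1e-3 error rates — while recall on the reference simulation
rises from ~0.96 to ~0.99.

**Links**: each molecule contributes one consensus allele per overlapped het
site (base quality-free in the simulator; disagreeing duplicate reads drop
the site); adjacent-in-molecule site pairs increment cis (equal alleles) or
trans counters. The link weight per net observation is
`w = log10((1−ε)/ε)` with ε = 0.02, an assumed allele-observation error rate
that prices in error sources beyond sequencing substitutions (local
misassignment of reads to molecules); `log_odds = (n_cis − n_trans)·w`.

**Block assembly**: links are processed in decreasing |log_odds| (ties by
variant index) through a parity-tracking union-find; the sign of the link
fixes relative orientation. Links with |log_odds| below `min_block_logodds`
(default 2w ≈ 3.4, i.e. at least two concordant molecules) never join —
weakly connected junctions become block boundaries, and blocks are reported
as maximal runs of consecutive variants in one component so phase sets are
contiguous. A refinement sweep then tests all 2⁵ flips of each 5-variant
window and keeps the max-concordance configuration, repairing isolated flips
(the short-switch mode) at bounded cost; on a 16-variant instance the result
matches the exhaustive 2¹⁶ search. Orientations are normalized so each
block's first variant is 0; all evaluation metrics are invariant to per-block
global flips. Single-variant blocks are emitted unphased and excluded from
N50.

Two qualitative behaviours are locked in tests: phase-block N50 grows with
heterozygosity at fixed molecule length (3-point ladder), and two target het
sites are phased together exactly when molecules span the largest inter-het
gap — either directly (long molecules) or by stitching through intervening
het sites (2×2 grid of molecule length × het density).

## Structural variants

**Barcode overlap.** Windows (10 kb) index which barcodes have molecules
overlapping them. For every window pair separated by more than
`min_separation` (30 kb) on one chromosome, or on different chromosomes, the
shared-barcode count is tested against a hypergeometric null
`P(X ≥ k | N, |bc(A)|, |bc(B)|)` with Benjamini–Hochberg correction over all
tested pairs (α = 0.01). One refinement is essential at a 30 kb separation
floor: sharing attributable to a *single contiguous molecule* covering both
windows is excluded from k (computed exactly from per-molecule window ranges
by 2-D cumulative sums), because exponential 50 kb molecules routinely span
30–200 kb and are not junction evidence; distinct same-barcode molecule
clusters on the two sides are. Significant diagonally-adjacent pairs merge
into one call (breakends at the inner window edges, score = −log₁₀ p); type
is assigned from molecule depth between same-chromosome breakends (<0.75× →
DEL, >1.25× → DUP, else INV; cross-chromosome → TRA). The presence/absence
null ignores molecule-count variation per window by design — it is robust to
molecule-length variation and exactly testable against enumeration.

**Coverage segmentation.** Windowed depth (1 kb molecule depth by default;
read depth at low coverage) is normalized to log2 of the genome median and
recursively split at least-squares changepoints. Splitting continues while
the SSE gain exceeds a BIC-style floor `3·σ²·log n` (σ from successive
window differences); because molecule-scale autocorrelation makes that floor
permissive on smooth signals, adjacent segments whose means differ by less
than 0.3 are re-merged afterwards (CBS-style pruning). Segments of ≥
`min_size` with |log2| ≥ 0.4 become DEL/DUP calls; terminal segments are
eligible, covering telomeric events the overlap scan cannot see. Het
deletions sit at log2 ≈ −1, comfortably above the noise at 1 kb windows and
30×. Known limitation: tandem-DUP boundaries smear outward by about one
molecule length because junction-spanning molecules extend the elevated
region.

**Haplotype-resolved deletions** (50 bp–30 kb): molecules vote themselves
onto a block haplotype through their phased-site alleles; per-haplotype read
depth inside blocks is computed in 500 bp windows, and windows where one
haplotype drops below 0.2× its block median while the other stays ≥0.5×
become DEL calls labelled with the block haplotype (a per-block label, not a
global one). Outside blocks a total-depth drop to 0.3–0.7× of the genome
median yields an unlabelled candidate; the first and last window of each
chromosome are excluded because read-level coverage tapers there. Precision
of this detector is deliberately modest (sub-kb molecule-sampling dips do get
flagged); that trade-off mirrors how depth-based intermediate-size callers
behave in practice.

**Filtering and merging.** Calls with a breakend inside a segmental-
duplication mask interval (half-open) are demoted to CANDIDATE. The two
large-SV streams are unioned with secondary calls dropped at ≥50% reciprocal
overlap against the primary stream.

A coverage-ladder experiment pins the relative data requirements: down-
sampling reads from ~30× to ~0.5× extinguishes translocation detection (the
molecule floor of the barcode index empties) while ≥60% of large deletions
still segment out of read depth — balanced events need deep data, CNVs do
not.

## Evaluation metrics

* **N50**: largest L such that blocks ≥ L sum to half the total.
* **Switch errors**: within each called block, the agreement sequence against
  truth is scanned for sign changes; two changes enclosing ≤ `isolation_span`
  (default 5) variants form one *short switch*, an unpaired change is a
  *long switch*; both are rated per phased het variant. Unphased calls are
  excluded from denominators. The within-block correct rate is the mean over
  blocks of the agreement fraction after the optimal global flip; the
  gene-level rate applies the same logic to the variants of each gene's
  dominant phase set. The isolation span is a convention, exposed as a
  parameter.
* **Coverage metrics**: exact per-base depth tracks feed the depth histogram
  (counts sum to genome length), per-gene fraction of exonic bases at ≥10×
  (≥20× for exome-style analyses) at MapQ ≥ 30, and the two-track unique
  coverage gain (bases at ≥5×/MapQ ≥ 30 in exactly one track).
* **SV benchmarking**: large calls match at ≥50% reciprocal overlap (greedy
  one-to-one by overlap; translocations by both breakends within one window);
  intermediate calls are first merged by transitive closure of ≤50 bp
  breakpoint distance — transitive rather than pairwise, because chains of
  nearby calls should collapse to one event — then matched by the same 50 bp
  criterion.
* **Heterozygosity**: called het sites divided by non-N reference bases.

## Reproducibility

Every stage consumes a `numpy` Generator seeded from `SimConfig.seed`;
identical configurations give byte-identical FASTA/FASTQ/VCF/TSV/BEDPE
output and identical evaluation reports (asserted in tests). The reference
problem sizes — 10 Mb genomes for parameter recovery and SV detection, 6 Mb
for the heterozygosity ladder, 1 Mb for the two-het grid — keep the full
suite and the acceptance script within a few minutes on one CPU while
leaving every measured rate far from its small-sample noise floor.
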