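# Methods

## The discovery model

The pipeline treats SNP discovery in a polyploid transcriptome as a
filtering problem on mapper-style candidate records. Each record is one
observed difference between a genotype's reads and the reference contig
assembly: contig, 1-based start/end, reference and variant allele, variant
frequency (percent of reads at the column carrying the variant) and read
depth. Coordinates are 1-based and inclusive throughout; sequences are
transcript-strand only.

Two mechanisms generate candidate records with different frequency
signatures:

* a **true allelic SNP**, fixed within a genotype, is carried by every read
  of that genotype at the column — frequency exactly 100%;
* a **pseudo-SNP** from a collapsed homoeolog pair is carried only by the
  reads originating from one subgenome copy. If copy weights (expression
  shares) are `w`, the variant read count at depth `d` is binomial `(d, w)`,
  so the frequency concentrates around `100·w` and reaches 100% only with
  probability `w^d` — about `10^-15` at `w = 0.5, d = 50`.

The conservation rule (frequency must equal 100%) is therefore the key
polyploidy screen; depth ≥ 5 bounds the false-pass probability of shallow
columns (at `w = 0.5` a depth-5 column passes with probability `2^-5 ≈ 3%`,
and such sites are additionally suppressed by the self-screen when they
also appear in the reference genotype's own re-assembly).

### Rule cascade and accounting conventions

The reference self-screen removes contigs with indel self-variants, then —
from the survivors — contigs with ambiguous base calls (N in the consensus
or an N-allele self-variant); a contig failing both is counted once, in the
indel stage. Both percentages are reported against the initial contig
count. The cross-genotype cascade then runs indel/multi-base/N → depth →
conservation; stages are sequential (each consumes the previous stage's
survivors) but every percentage is reported against the count entering the
cascade, matching the accounting convention of the published narrative this
reproduces. Stage order is configurable; the default is the reporting
order above. Records on contigs that failed the self-screen are dropped
before staging and never appear in the accounting.

Percent rendering: nearest integer, with one decimal kept below 2% so small
classes do not round to "0%". One printed value in the source narrative
(953 of 51,405 shown as 1.8%) is 0.1 off any consistent nearest-rounding
scheme that also reproduces its neighbouring percentages; we render 1.9%
and regard the printed figure as a rounding artifact of the source.

Frequency equality to 100 is tested with tolerance 1e-9 on the percent
scale. Note that the table dialect prints frequencies with one decimal, so
a table round trip quantizes frequencies to 0.1% — the native record-level
pipeline keeps full precision.

### Classification, assay targets, masking

Survivors group by (contig, position, alternative base); the sharing class
is the number of genotypes in a group. Requiring an *identical* alternative
base for sharing is the conservative choice (a per-position grouping would
merge different substitutions); it is the default and the grouping key is
the single place this is encoded. A contig is excluded from assay output
when two candidate positions are strictly closer than 100 bp (ties at
exactly 100 bp are retained; the boundary is a documented choice). Masked
windows carry the two-base IUPAC code at the SNP and default to 50 bp
flanks, truncating (with a flag, never an error) at contig ends; the
90 ± 30 bp product-size constraint is annotated for downstream primer
design, which is deliberately out of scope.

## The read aligner/caller stand-in

The caller reproduces "call every difference" behaviour so the cascade has
realistic input: semi-global banded edit-distance placement (edlib, band =
10% of read length), deterministic tie-break to the lexicographically
smallest (contig id, offset), one record per column per non-reference
allele with frequency = 100·count/depth. N bases count toward depth as
their own allele class; deletions are the `-` allele at the deleted column;
insertions anchor at the preceding column with `-` as reference allele.
Equal-cost alignments that place an indel at a read boundary are normalized
to the substitution form (by re-alignment against the equal-length window);
a boundary insertion that survives normalization is ignored as unanchored.
Multi-column events are emitted per column, not aggregated into single
rows — a documented divergence from mappers that merge adjacent events.

## The synthetic generator

`SimConfig` defaults describe the study conditions the pipeline targets:
four genotypes (the first is the reference), three subgenome copies per
gene family, 2% inter-homoeolog divergence, contig lengths ~N(577, 220) bp
(clipped to [120, 3000]), 250-bp reads, Poisson coverage with mean 4x,
0.5% base-miscall rate, 1% per-run homopolymer indel rate (runs ≥ 3, one
base inserted or deleted), homoeolog expression shares (0.5, 0.3, 0.2),
30% of families collapsed, and planted allelic SNPs at 5 × 10⁻³ per base.
Planted SNPs are placed at homoeolog-invariant positions and applied to
every copy of a family simultaneously, so carriers are fixed for the
alternative base (keeping the truth labels mutually exclusive); carrier
sets are uniform over nonempty subsets of the non-reference genotypes.

Record-level mode skips alignment and draws depths Poisson(λ) (clipped to
≥ 1) and pseudo-site variant counts binomial in the expression weight of
the diverged copies; it exists so the cascade can be exercised at scale
without the aligner. Read-level mode feeds the same truth through FASTQ and
the caller. What the generator does *not* model: flowgram-level 454 noise,
quality-score variation (a constant quality is written), chimeric reads,
expression variation between genotypes, partial-length transcripts, and
uncovered contig tails are possible under uniform read starts. Passing
tests therefore demonstrate correctness of the pipeline's logic under the
stated generative model, not performance on any particular real library.

## Marker genetics

Segregation: SR is oriented parent-A over parent-B counts (numerator =
first-listed parent, configurable); the distortion test is a plain 1-df
chi-square against 1:1 over the homozygous classes, no continuity
correction, α = 0.05 — the test is an extension beyond the ratio itself and
is labelled as such in output. Markers with heterozygote fraction ≥ 0.4
(default) are flagged as probable multi-locus amplification. SR is reported
as undefined (not an error) when the parent-B count is zero.

Diversity coding: one indicator column per observed allele state per
marker; Null codes 0 across the marker's columns (absence of
amplification), missing codes NaN and is handled pairwise-complete in Dice
(columns where either individual is missing are dropped for that pair).
Het defaults to its own state column, since melt-curve analysis
distinguishes the heterozygous curve as a class of its own;
constituent-allele expansion (`A/G` → both columns) is available where
constituents are known. Dice similarity with an empty union is defined
as 0.

UPGMA operates on 1 − S with size-weighted average linkage and merge
height d/2; ties break on the lexicographically smallest pair of cluster
labels (each cluster keyed by its smallest member), which makes dendrograms
reproducible where the classical software leaves the order unspecified.
Newick output carries branch lengths; round-tripping through an independent
parser preserves topology and heights to 1e-9.

## Scales used in the validation suite

The test and acceptance runs use desk-scale problem sizes chosen to make
the statistics decisive while staying fast: 50 gene families at 50x depth
(≈600 planted pseudo-SNP sites, ≈250 fixed-SNP records) for the recovery
check, 10,000 random records for the rule-cascade oracle, all 4,096
length-6 vector pairs for Dice, 3–5-taxon exhaustive oracles for UPGMA,
and 1,000 markers × 136 individuals for the chi-square calibration. The
published-scale totals (the 9,448-locus arithmetic, the sequencing-table
derivations, the 140-allele diversity accounting) are recomputed from the
printed per-stage inputs embedded in `polysnp.datasets`; the diversity
panel itself is a synthetic stand-in table whose distinct-state inventory
realizes the published partition, as the original per-line calls are not
available.

## Known limitations

* The aligner is a deterministic stand-in, not a reimplementation of the
  original mapper's scoring; proprietary aggregation of multi-base events
  is not mirrored.
* The conservation filter is exact-equality by design; real pipelines with
  frequency noise would need the record source to report exact counts, as
  mapper header files do.
* Contig-level statistics (self-screen) assume the self-variant table and
  the consensus FASTA describe the same assembly build.
* No linkage-map construction, no primer picking, no bootstrap support on
  dendrograms.
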