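# polysnp

SNP discovery in polyploid transcriptomes, built for the situation where a
reference genome does not exist and markers must be mined from EST contig
assemblies — as in cultivated oat (*Avena sativa*, 2n = 6x = 42), whose three
subgenomes (A, C, D) carry homoeologous copies of most genes.

## The problem

When a polyploid transcriptome is assembled de novo, homoeologous gene
copies frequently collapse into a single contig. Re-mapping reads against
such a contig then reports a "polymorphism" at every inter-subgenome
difference. These **pseudo-SNPs** are not allelic variation — they segregate
nowhere — and they can vastly outnumber real SNPs. `polysnp` implements a
filter cascade that exploits the one signal that separates the two: a true
allelic SNP is *fixed within a genotype* (every read carries it, variant
frequency = 100%), while a collapsed homoeolog site is supported by only the
subset of reads that came from one subgenome copy (frequency < 100%).

Given a reference contig assembly and per-genotype candidate-variant tables
(mapper-style records: contig, position, ref/var base, variant frequency,
read depth), the pipeline:

1. **screens the reference** against its own re-assembly, dropping contigs
   with indel self-polymorphism, then contigs with ambiguous (N) calls;
2. **filters cross-genotype records**: indel/multi-base/N events, then
   depth ≤ 4, then frequency < 100% (the conservation filter);
3. **classifies survivors** by genotype sharing — how many genotypes carry
   the identical alternative base at the identical coordinate (class 1, 2, 3);
4. **selects assay targets**, excluding contigs with two candidates less
   than 100 bp apart, and emits each remaining SNP as a dbSNP-style FASTA
   window with the site masked by its two-base IUPAC code (A/G → R, C/T → Y,
   …) and a 90 ± 30 bp amplicon-size constraint for primer design.

Downstream marker genetics are included: segregation-ratio scoring with a
1-df chi-square distortion flag for recombinant inbred lines, multi-state
melt-curve allele coding (In/Del/Het/Null) into a binary matrix, Dice
similarity S = 2a/(2a + b + c), and UPGMA clustering with Newick output.

A synthetic hexaploid-like transcriptome generator (`polysnp.simulate`)
plants labelled allelic SNPs, collapsed-homoeolog pseudo-SNPs and sequencing
errors, at either read level (FASTQ, through the built-in banded aligner and
caller) or record level, so every stage can be validated against exact
ground truth without any external data.

## Worked example

Simulate four genotypes (30 gene families, two subgenome copies, 40% of
families collapsed, balanced homoeolog expression, 30x depth, no sequencing
error), then run the discovery pipeline:

```
$ polysnp simulate --config sim.yaml --out-dir sim
wrote 49 reference contigs, 764 variant records, 268 truth entries to sim

$ polysnp run --config pipe.yaml
SNP discovery attrition
  reference_indel: 0 (0.0%) removed, 49 remaining of 49
  reference_ambiguous: 0 (0.0%) removed, 49 remaining of 49
  indel: 0 (0.0%) removed, 627 remaining of 627
  depth: 0 (0.0%) removed, 627 remaining of 627
  conservation: 411 (66%) removed, 216 remaining of 627
131 candidates ({"1": 61, "2": 55, "3": 15} by class); 40 assay targets
```

Reading the output: 627 candidate records entered the cascade; with no
errors and deep coverage, all attrition happens at the conservation stage —
the 411 removed records are almost entirely collapsed-homoeolog pseudo-SNPs
whose frequencies sit near 50%. The 216 surviving records group into 131
candidate SNP loci, of which 61 distinguish one genotype from the reference,
55 two, and 15 all three. Crowded contigs are excluded and the rest are
written as masked primer-design targets:

```
>c00002_0_21 ref=C alt=G class=1 window=1-71 product_size=90+/-30 truncated
ACAATTGTAATCCTTCGCTCSCTGAACAAATAATCGCAATTGTTGTCAAGAACCGTTAAATCGGACAGAAT
```

The `S` at offset 21 masks the C/G SNP; the window is flagged `truncated`
because the site sits closer than one flank length to the contig start.

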