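# ampsel

Genotyping and marker-assisted selection (MAS) from simplified amplicon
sequencing, for plant-breeding programs.

Breeders increasingly genotype seedlings with pooled amplicon libraries
built by a simplified one-step PCR: tailed target primers amplify each
marker locus, while a second primer set adds flow-cell binding sites and a
unique dual 8-nt index per sample. After paired-end sequencing, the desk
side of the workflow is entirely computational, and that is what this
package implements:

1. **readprep** — demultiplex read pairs by dual index, trim adapters and
   low-quality tails, merge mates over their overlap, and discard merged
   reads shorter than 80 bp (primer dimers).
2. **assign_count** — assign each merged read to a marker by matching both
   target primers, count reads per allele (allele = merged-read length in
   bp for SSR/indel markers; exact sequence stacks for SNP haplotypes),
   extract the four most common alleles with frequencies, and export
   digital electropherograms (length-vs-frequency traces).
3. **calling** — ploidy-aware genotype calls with stutter attribution and
   largest-remainder dosage apportionment, plus MAS decisions: a sample
   carries a target allele iff its frequency strictly exceeds the
   marker's threshold, and is selected iff it carries every required
   marker.
4. **qc** — per-marker read proportions, on-target fraction, and
   first-allele-frequency repeatability between replicate runs.
5. **simulate** — a synthetic library generator (dosage-weighted allele
   sampling, geometric SSR stutter, sequencing error, incomplete
   tail-only products, primer dimers, optional index hopping) so every
   stage can be exercised without real reads.

## The statistics in brief

For a sample with ploidy *p* carrying allele *a* in *d* copies, the
frequency of *a* among that marker's reads concentrates around *d/p* —
0.5 for a diploid heterozygote, 2/3 for a triploid duplex — minus the
mass lost to stutter. Genotypes are therefore read off the top-allele
frequencies: alleles above a presence threshold (default 0.10, after
folding single-step stutter) are real, and *p* copies are apportioned
among them by largest remainder (every retained allele gets ≥ 1 copy;
this matches exhaustive L1-minimisation over dosage vectors, which the
test suite verifies). MAS skips genotyping entirely and thresholds the
target-allele frequency per marker.

## Worked example

Simulate three diploid samples at one SSR (repeat unit 2 bp, target
allele 127, carrier threshold 0.30) and run the pipeline:

```
$ ampsel simulate --panel panel.yaml --truth truth.tsv --depth 500 --seed 4 --out reads
dimer=75  hopped=0  incomplete=75  on_target=1350

$ ampsel run --config run.yaml
selected: s000,s001
```

where `truth.tsv` gives genotypes 127/127, 127/133 and 133/133, and
`run.yaml` points at the panel and the simulated FASTQ files. The allele
table shows the recovered frequencies — the homozygote near 0.88, the
heterozygote split 0.51/0.36 with small stutter peaks two bases below
each allele:

```
sample_id  marker  total_reads  marker_reads  allele1  freq1  allele2  freq2  allele3  freq3  allele4  freq4
s000       SSR1    450          450           127      0.88   125      0.05   129      0.02   123      0.02
s001       SSR1    450          450           127      0.51   133      0.36   125      0.04   129      0.02
s002       SSR1    450          450           133      0.88   131      0.04   129      0.03   135      0.03
```

`genotypes.tsv` calls 127/127, 127/133 and 133/133 (all correct), and
`selection.tsv` keeps s000 and s001 — the two samples whose 127-bp
target-allele frequency exceeds 0.30 — while s002 fails at SSR1.

The same calling/selection stages run directly from a frequency table
with `ampsel tables --panel P --allele-table T --out DIR`; the packaged
reference tables (`ampsel.reference`) are loaded that way.

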