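# Methods

This note documents the models, parameter choices, and numerical
conventions behind `ampsel`, and what the synthetic-data experiments do
and do not demonstrate about real libraries.

## Library construct and size arithmetic

A simplified one-step amplicon library molecule is, from the outside in:
flow-cell binding site (P5), 8-nt i5 index, 33-nt forward anchor tail,
the primer-inclusive target amplicon, the reverse complement of the
34-nt reverse anchor tail, the i7 index, and the P7 site. The panel
module models two derived sizes:

* `expected_library_size = ref_amplicon_length + extension_length`,
  with `extension_length` defaulting to 135 bp. The extension is taken
  as a single given constant rather than a sum of part lengths, because
  the outer parts overlap the second primer set and the effective
  added length is what a gel shows (242–271 bp for 107–136 bp target
  amplicons).
* `expected_incomplete_size = ref_amplicon_length + |r1_tail| + |r2_tail|`
  for products amplified by the tailed target primers alone. These carry
  no index or flow-cell sequence, cannot be sequenced, and appear only
  as a short background band (174 bp upward for the panels here).

Panel validation is strict: duplicate marker names, duplicate index
pairs, malformed DNA, thresholds outside (0, 1), and prefix-nested
forward primers are all hard errors. The last one deserves emphasis: if
one marker's forward primer is a prefix of another's, read assignment is
ambiguous by construction and every downstream frequency is corrupted,
so it is never merely a warning.

## Synthetic library model

The simulator emulates what the pipeline must be robust to, not the
full chemistry of PCR.

* **Read classes.** Per (sample, marker) the configured depth is split
  exactly (rounded fractions) into primer dimers (defaults 5%),
  incomplete tail-only products (5%), and on-target molecules. Dimers
  are the two target primers joined with no insert (< 80 bp), carry
  valid indexes, and must be removed by the length filter. Incomplete
  products are emitted with all-N index fields: real instruments never
  deliver them, so the simulator represents them as untrackable
  background that demultiplexing must shunt aside.
* **Allele sampling.** Each on-target read's allele is drawn from the
  truth dosages (multinomial with probabilities dosage/ploidy), so
  observed frequencies are binomial around d/p by construction.
* **Stutter.** SSR reads slip downward with probability `stutter_prob`;
  the number of repeat units lost is geometric with continuation
  `stutter_continue` (P(k) = stutter_prob · (1−c) · c^(k−1)), and a
  single-unit upward slip occurs with `plus_one_prob` (default 0.02).
  Geometric decay is the standard single-locus slippage model; large
  `stutter_prob` with overlapping alleles reproduces the pathological
  "stutter stronger than the true band" regime. No quantitative stutter
  rates are published for these markers, so the defaults (0.1 / 0.4)
  are free parameters chosen to produce visible but resolvable ladders;
  the calibration studies state their settings explicitly.
* **Sequencing error.** Uniform per-base substitution (default 0.003),
  applied independently to each mate. Bases carrying a simulated error
  are written at Q15 against a Q30 background, so quality trimming has
  a real signal without a full platform error profile.
* **Read geometry.** PE150: read 1 covers the amplicon and runs through
  into the reverse-anchor adapter and outer structure; read 2 mirrors it
  from the other strand. This makes adapter trimming and outie merging
  load-bearing rather than decorative.
* **Fillers.** SSR inserts tile the repeat motif between the primers, so
  stutter changes length by whole motifs; non-SSR inserts use a fixed
  pseudo-random sequence derived from the seed and marker name, so
  haplotype stacking is meaningful.
* **Index hopping** swaps a read's i7 with another sample's at
  `hop_rate` (default 0). Hopped reads usually form invalid index pairs
  and land in "unassigned"; no correction is attempted anywhere.

Everything is deterministic given (panel, truth order, config, seed):
identical inputs give byte-identical FASTQ.

What the simulator does **not** model: PCR-cycle chemistry and
concentration-dependent yields, chimeras, platform-specific quality
profiles, GC bias, and inter-marker amplification competition. Passing
tests therefore demonstrate the pipeline's correctness and calibration
under controlled noise, not performance on any particular instrument
run.

## Read preparation

* **Demultiplexing.** Exact dual-index match by default
  (`max_index_mismatch = 0` — conservative for 8-nt unique-pair
  designs). With a tolerance, both indexes must match within it; the
  strictly smallest total Hamming distance wins and equidistant samples
  leave the pair unassigned. Index information comes from Illumina-style
  header comments (`...:i5+i7`) or separate index-read files.
* **Trimming.** Adapter read-through (the reverse complement of the
  opposite anchor tail) is removed wherever it matches with at most one
  mismatch per 10 nt and at least 6 nt of overlap; then trailing bases
  below Q20 are stripped. Substitution-only matching throughout — allele
  identity is length, so nothing may indel.
* **Merging.** All placements of revcomp(read 2) against read 1 are
  considered in order of decreasing overlap, including outie/staggered
  placements; the first overlap of ≥ 10 nt with mismatch density
  ≤ 0.05 is accepted (ties on length resolved toward fewer mismatches),
  and disagreeing bases take the higher-quality call. In the outie case
  the dovetail overhangs are adapter read-through and only the overlap
  is kept. This mirrors the behaviour of overlap-based mergers used on
  short amplicons without promising bit-exact equivalence to any
  external tool. Unmerged pairs are dropped, not rescued: allele length
  is only defined on merged amplicons.
* **Length filter.** "Shorter than 80 bp" is discarded, so exactly
  80 bp is kept. Every stage counts what it drops; the pipeline's
  conservation ledger (input = assigned + unassigned; assigned = kept +
  trim-dropped + merge-failed + length-filtered) is asserted in tests.

## Assignment and counting

A merged read is assigned to a marker only if its prefix matches the
forward primer **and** its suffix matches the reverse complement of the
reverse primer, each within 2 substitutions; the fewest-total-mismatch
marker wins and exact ties are unassigned. Allele length is the full
primer-inclusive merged length — panel sizes include primers, so no
stripping happens before measuring. The four most common alleles are
reported with frequencies over the marker's reads (not the sample
total); count ties rank the smaller length first, including at the
fourth slot. Electropherograms keep every observed length, which is what
makes stutter ladders visible below a long-repeat allele. SNP markers
stack reads by exact sequence; sequencing errors create singleton stacks
that never reach the top two at realistic depths, so no alignment is
needed, and stacks are named from a haplotype catalog (matching at the
marker's variant offsets) or HAP1, HAP2, … by cohort-wide count.

## Genotype calling

Empirically, a diploid homozygote shows Freq1 near 0.8 and a
heterozygote near 0.4, the remainder sitting in stutter and background.
The calling defaults are placed around those anchors:

| parameter | default | role |
|---|---|---|
| presence_threshold | 0.10 | an allele below this is noise/stutter remnant |
| homo_threshold | 0.65 | lone candidate at/above this is a confident homozygote (midpoint between the 0.4 and 0.8 anchors) |
| het_floor | 0.20 | minimum second-allele support for heterozygosity |
| stutter_ratio | 0.5 | max child/parent ratio attributable to slippage one unit below |
| min_marker_reads | 50 | below this, calls are flagged "low-depth" but attempted |

All are judgement-based and config-exposed. Stutter attribution runs
first: an entry exactly one repeat unit below a more frequent entry with
ratio ≤ `stutter_ratio` is folded into it (one-directional, single-step).
A pair one unit apart whose ratio exceeds the threshold is flagged
"stutter-ambiguous" and never silently inverted — such cases (a stutter
band rivalling or exceeding its parent at long-repeat loci) are exactly
the ones resolved by a human reading the electropherogram, and no
algorithmic rule for them is defensible from frequencies alone.

Polyploid dosage: retained alleles are renormalized and the ploidy is
apportioned by largest remainder with a minimum of one copy per allele;
shedding/granting steps use exact marginal-|quota − dosage| costs with
ties resolved toward loading the higher-frequency allele. The test suite
checks this against exhaustive search minimising Σ|freq·p − d| over all
dosage vectors (all retained sets of size ≤ 4, ploidy ≤ 6). More
retained alleles than the ploidy is flagged "over-allelic" and truncated.

## Marker-assisted selection

The carrier statistic is the summed frequency of the marker's target
alleles over the full allele table (summation is the contract when
several favorable alleles exist). The comparison is strictly greater
than the per-marker threshold — boundary equality is non-carrier.
Thresholds live on the marker, not in global parameters, because
stutter-prone loci need lower criteria (0.10 rather than 0.30 in the
packaged pear panel). Dominant (presence/absence) markers are judged on
the marker's share of the sample's reads instead, and get no genotype
call. Selection is the conjunction of carrier decisions over the
required markers; a missing decision is a hard error, and an empty
requirement list vacuously selects everyone.

## QC

Per-marker proportions are marker reads over total sample reads,
cohort-averaged with equal sample weights; amplification bias is
summarised as the max − min spread of per-marker proportions (a scalar
chosen here; the underlying per-marker list is also reported).
Repeatability is the correlation of first-allele frequencies across
samples shared by two replicate runs — Pearson by default with Spearman
as a config choice, since no particular statistic is canonical — and
requires at least three shared samples.

## Calibration studies and problem sizes

`ampsel.scenarios` packages four end-to-end studies (simulate → demux →
trim/merge → assign/count → top alleles) on a one-SSR panel at depth
2000 per sample: homozygous diploids and heterozygous diploids (stutter
0.15, continuation 0.4, error 0.003, repeat unit 2, 50 samples each in
the acceptance script), and balanced (1/1/1) and duplex/simplex (2/1)
triploids (stutter 0.1, repeat unit 3, 30 samples each). The test suite
runs the same scenarios at 8 samples per scenario; at depth 2000 the
across-sample mean has negligible sampling noise, so the smaller cohort
tests the same anchors at full tolerance. Recovered means sit near 0.83
(homozygous), 0.43 (heterozygous), 0.29 (third allele of balanced
triploids) and 0.60 (duplex allele of 2/1 triploids): stutter moves each
anchor a few points off the ideal d/p, in the same direction real
libraries show.

## Known limitations

* Stutter-dominant loci are flagged, not resolved; a breeder must still
  inspect the electropherogram.
* The merger is not bit-compatible with any specific external tool;
  only its acceptance contract (overlap ≥ 10, density ≤ 0.05, outies
  allowed) is guaranteed.
* Repeatability on real replicate libraries and real per-marker read
  proportions depend on wet-lab factors the simulator does not model;
  the qc module is validated on constructed and simulated inputs only.
* Frequencies reconstructed from a 2-decimal report table are rounded;
  replayed decisions match the printed ones, but recomputed counts are
  approximations.
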