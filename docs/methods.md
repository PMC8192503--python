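# Methods

`edscape` implements a desk-scale A-to-I RNA-editing analysis pipeline of
the kind used for tissue-wide editing surveys: matched DNA/RNA alignments
are reduced to filtered base counts, editing sites are identified in two
rounds with homozygosity, evidence, paralog and replication filters,
hyper-edited reads are rescued by base-transformed realignment, and the
resulting site set is annotated and summarised (landscape statistics,
region-specificity classes, miRNA-seed alterations, cross-species
differential editing).  A built-in generator produces a synthetic study
with planted ground truth so that every stage is testable without
downloads.  This note records the models, the parameters that matter, and
the design decisions taken where the procedure was genuinely open.

## Editing model and site calling

A-to-I editing is read by sequencers as A→G on the edited strand (T→C on
the opposite genomic strand).  The per-site editing level is G/(A+G) over
RNA reads covering the site after filtering.  Evidence filters follow the
two-round scheme:

**Pileup filters.** PCR duplicates are removed per sample, keeping one
read per (chromosome, start, strand) — the highest quality-sum read, ties
broken by lexicographically smallest read id.  RNA bases contribute to the
pileup only if their Phred score is ≥ 30 and they lie outside the first
and last 6 bases of the read; DNA bases are quality-filtered but not
end-clipped (clipping guards against splice/adapter artefacts specific to
RNA alignments).  "Uniquely mapped" is operationalised as MAPQ ≥ 30 at
ingest.

**Round 1 (de novo), per sample.**
1. *Genomic homozygosity*: DNA depth ≥ 10 and major-allele fraction
   ≥ 1.0 (strict) for the reference base.  The strict default is
   conservative and fully testable; it is configurable
   (`dna_major_allele_min_frac`) because at low replication a single
   surviving DNA sequencing error otherwise vetoes a true site (the test
   suite exercises 0.95 on its two-samples-per-region fixture).
2. *RNA evidence*: ≥ 3 variant reads and level ≥ 5% from the filtered
   pileup.  Sites with two distinct variant bases each reaching the
   evidence floor, or tied variant counts, are dropped as ambiguous.
3. *Paralog guard*: variant-supporting reads are realigned with the
   seed-and-extend aligner; a read qualifies if its unique best placement
   overlaps the site.  Sites with < 50% qualifying reads are discarded.
4. *Replication*: a site enters the master list only if ≥ 2 samples pass
   criteria 1–3 independently (support is counted over fully qualifying
   samples, not merely covered ones).

**Round 2 (re-quantification).**  Every master site is re-quantified in
every sample with ≥ 10 edited+unedited reads; one variant read suffices to
flag a sample as edited.  Covered-but-unedited records (level 0) are kept
so pooled denominators and Fisher tables are correct.  A 4-read floor
(`known_min_total`, "known" mode) serves external low-depth datasets.

Strand and mismatch type are assigned from the host gene when the site
lies in exactly one gene's span; for intergenic or ambiguous sites the
strand that reads A-to-G is preferred, else '+'.

## Seed-and-extend realignment

A BLAT-style realigner at desk scale: every k-mer (k = 16) of the read is
looked up in a sorted 2-bit k-mer index of the genome, each hit proposes a
diagonal, and diagonals are scored by full-length ungapped mismatch count;
placements with mismatch fraction ≤ 0.1 are reported on both strands.  A
hit is "unique" when it is the sole best-scoring placement.  With ≤ 4
mismatches in a 100-bp read an exact 16-mer seed always exists
(pigeonhole), so the seed-based definition coincides with an exhaustive
scan in the regime the paralog filter operates in; heavily diverged
placements near the 10% budget may additionally require a shared seed,
which is the intended behaviour for a seeded aligner.

## Hyper-editing recovery

Reads too densely edited to align are recovered by collapsing the editing
channel: the read and genome have all As replaced by Gs and the read is
realigned; antisense transcription is handled by aligning the reverse
complement of the transformed read against the T→C-transformed forward
genome (the algebraic mirror of A→G on the other strand).  After restoring
the original sequence at the unique best placement, a read is accepted if
A→G mismatches ≥ 5, the A→G share of all mismatches is ≥ 0.6, and non-A→G
mismatches are ≤ 5% of the read.  These thresholds are configurable
because the upstream literature delegates them to the recovery tool rather
than fixing them.  A read that restores with zero mismatches passes
through unchanged: it is simply alignable, not hyper-edited, and
discarding it would lose valid coverage.  Recovered reads are merged with
the direct alignments before duplicate removal, so they are clipped and
quality-filtered exactly like other RNA reads.

## Landscape statistics

* **Pooling** sums G and A+G counts, so a pooled level is always the
  coverage-weighted mean of member levels, and "overall editing" of a
  sample is a pool over all sites.  Pooling is associative over nested
  groupings.
* **Site-count normalisation** is sites per million uniquely mapped reads.
* **Expression normalisation** uses median-of-ratios size factors
  (per-gene geometric-mean reference over genes positive in all samples).
* **Clustering tendency**: a site is clustered when ≥ 3 class-mates
  (including itself) fit in a 100-bp window, computed by a sorted sliding
  scan.  The threshold is "at least three" by default with `min_sites`
  configurable, because the source material states both "at least three"
  (figure legend) and "more than three" (text) for the same statistic.
* **PCA** on levels is centred but not scaled (levels share units), after
  gating to sites with ≥ 10 reads in all columns so the matrix is
  complete-case.
* **Rank tests** use exact enumeration for untied pooled samples of ≤ 12
  observations and the tie-corrected, continuity-corrected normal
  approximation otherwise; at the switch point the two agree within 0.02.
* **Highly/lowly edited** strata use level > 0.75 and < 0.25.
* The coefficient of variation across region means uses the population
  standard deviation (the choice is not fixed by the source; it is
  documented here and configurable in spirit via `gate_genes`).

## Region specificity

After an expression gate (host gene CV < 1 across regions and normalised
expression ≥ 10 everywhere) and a coverage gate (pooled total ≥ 10 reads
in ≥ ⌈2/3·n⌉ regions), each site receives exactly one label, evaluated in
the order region-enriched → group-enriched → region-enhanced →
low-specificity.  All margins are absolute percentage-point differences
(consistent with the cross-species rule), the minimum level is 25%, the
margin 20 points, and group sizes run from 2 to ⌊n/3⌋ (2–4 at twelve
regions), taking the smallest qualifying set with ties broken by region
name.  The fixed evaluation order is what keeps the reported categories
disjoint; the best group of size s is always the top-s regions by level,
so a prefix scan is equivalent to subset search (verified against a
brute-force oracle in the tests).

## miRNA seed-site alteration

The 13-nt mRNA-sense flank (6 nt each side) of a 3′-UTR site is scanned
against mature-miRNA seeds, once with A and once with G at the centre.  A
window matches when it is the exact Watson–Crick reverse complement of the
seed (no G·U wobble) and covers the edited position — a match not covering
the centre cannot be altered by the edit.  The default seed is positions
2–8 (7 nt); the literal 2–7 (6 nt) scheme is selectable because the
defining sentence in the source ("a seed (7 bp) … positions 2–7") is
internally inconsistent.  Flanks are read from genomic sequence; the rare
junction-spanning flank of a spliced UTR is not reconstructed.

## Cross-species differential editing

At conserved sites (consumed as a precomputed one-to-one coordinate map),
per-region pooled 2×2 tables (edited/unedited × species) are compared with
a two-sided Fisher exact test (point-probability rule); a site is
species-biased when |Δlevel| ≥ 20 percentage points and p < 0.01.  No
multiple-testing correction is applied by default, matching the raw-p
convention of the source analysis; Benjamini–Hochberg is available.  A
(site, region) needs ≥ 10 pooled reads per species to be testable —
mirroring the quantification gate, since the source states no explicit
floor.

## The synthetic study

The generator emulates the input side of a brain-wide editing survey:

* **Genome**: random chromosomes (default 2 × 200 kb) carrying
  single-transcript gene models (non-overlapping exons, CDS divisible by
  3, ATG start forced, terminal UTRs) and SINE-like repeat copies tiled at
  25% of the genome.  Copies derive from per-subfamily consensus sequences
  (Pre0_SS, PRE1f, … with abundances mirroring the porcine PRE family) and
  are mutated at 10% divergence — enough that 100-bp reads place uniquely,
  as they do in real, diverged SINE families.
* **Truth set** (default 500 sites): class mix 60% repeat, 20% intron, 8%
  3′-UTR, 3% 5′-UTR, 6% CDS-recoding, 3% CDS-synonymous.  Repeat and
  intron levels draw from Beta(1, 9) (mostly-low levels), UTRs from
  Beta(1, 6); recoding sites draw from Beta(2, 2) with 30% "Q/R-like"
  sites at 0.99–1.0, and one recoding site is forced to ≥ 0.99 in all
  regions.  Candidate As are weighted by the ADAR-like neighbour signature
  (G at +1 weighted 2×, G at −1 weighted 0.5×); repeat sites are sampled
  3–6 per copy inside 100-bp anchor windows so they cluster.  40 repeat
  sites (≈ 8%, the order of the region-specific fraction reported for real
  brain) are planted region-enriched: level 0.5 in one region, 0.05
  elsewhere.  50 heterozygous A/G SNPs are planted at genic A positions
  disjoint from sites; all animals are heterozygous and both alleles are
  expressed.
* **Reads**: strand-specific RNA at 60× per sample (read strand = host
  gene strand, '+' intergenic; coverage is uniform genome-wide, the toy
  analogue of ribo-depleted total RNA over pre-mRNA, so intronic and
  repeat sites are observable), DNA at 60× per animal.  A read covering a
  site carries the edited base with probability equal to the region's true
  level, independently per read (no molecular phasing).  Qualities put 5%
  of bases below Q30; sequencing errors are uniform at 0.1%; 5% of reads
  are duplicated exactly.  0.5% of RNA reads are designated hyper-edited
  molecules: every sense A is edited with a per-molecule probability drawn
  from U(0.2, 0.5) (minimum five edits), and these reads are emitted to
  the unmapped FASTQ instead of the SAM.  Hyper-edited molecules are kept
  a small minority so that their off-site A→G load does not masquerade as
  de novo sites.
* **Determinism**: one `rng_seed` drives everything; identical
  configurations produce byte-identical FASTA/GTF/BED/SAM/FASTQ/TSV.

What the generator does **not** emulate — and hence what green tests do
not certify about real data: splice-junction reads and indels, coverage
non-uniformity and 3′ bias, strand-assignment errors, correlated error
profiles (qualities are independent of error events), allele-specific
expression at SNPs, molecularly phased editing, repeat families recent
enough to defeat unique mapping, and real miRNA/expression data (the
specificity expression gate and the miRNA catalogue are exercised with
synthetic tables).

## Problem sizes used in the checks

The end-to-end checks run the full default study (2 × 200 kb, 12 samples,
60×, ≈ 2.9 M RNA reads); hyper-recovery is additionally checked error-free
on a 100-kb single-chromosome study, and level convergence on a 20-kb
study at 2000× across six pooled libraries, where ±0.02 is a > 4σ bound
for every planted level.  Oracle comparisons enumerate all 2×2 tables
with row margins ≤ 30, 50 random 200-site clustering sets, 500 random
12-region level matrices, and 1,000 random flanks × 50 seeds.

## Known limitations

* The aligner is ungapped; indels, splices and soft-clips are out of
  scope, and SAM ingest assumes simple `<n>M`-style alignments.
* Duplicate removal is single-end samtools-rmdup-like; at high depth it
  collapses coincidental same-start fragments too, which lowers effective
  coverage (levels remain unbiased because retention is independent of
  the edited base).
* Multi-transcript genes are not modelled; annotation precedence
  (CDS > 3′-UTR > 5′-UTR > intron > noncoding > intergenic) resolves
  overlapping single-transcript models deterministically.
* Fisher tests use raw p-values by design; at genome scale a correction
  option is provided but off by default.
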