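# edscape

A-to-I RNA-editing landscape analysis at desk scale: from matched DNA/RNA
alignments to editing-site calls, hyper-edited read recovery, annotation,
region-specificity classes, miRNA seed-site alteration predictions, and
cross-species differential editing — with a built-in synthetic-data
generator that plants ground truth so the whole pipeline is testable
without any downloads.

## Who this is for

Adenosine deaminases (ADAR1/ADAR2) convert adenosine to inosine in
double-stranded RNA; sequencers read inosine as guanosine, so editing
appears as A→G mismatches between RNA reads and the DNA genome of the same
individual.  Distinguishing genuine editing from SNPs, sequencing error
and misalignment is the central methodological problem.  `edscape` is for
people who want a small, fully inspectable implementation of the standard
evidence chain used in tissue-wide editing surveys — e.g. to prototype
filter settings, teach the method, or validate parts of a production
pipeline against planted truth.

## The method in brief

Per site and sample, the editing level is

    level = G / (A + G)

over quality-filtered (Phred ≥ 30), end-clipped (6 bp), deduplicated RNA
reads.  **Round 1** calls a site de novo when, in ≥ 2 samples
independently: the DNA is homozygous reference at ≥ 10 reads; ≥ 3 variant
reads reach level ≥ 5%; and ≥ 50% of variant reads realign uniquely to the
site (paralog guard, via a built-in seed-and-extend aligner).  **Round 2**
re-quantifies every master-list site in every sample with ≥ 10 covering
reads, down to single-read edited calls.  Reads missed by direct alignment
because of hyper-editing are rescued by collapsing the editing channel
(read and genome A→G, antisense via the T→C mirror), realigning, and
restoring the original sequence.  Downstream, sites are annotated (genic
region, repeat subfamily, recoding consequence such as `Q607R`), pooled by
region, classified for region specificity (enriched / group-enriched /
enhanced at a 25% level floor and 20-point margin), scanned for miRNA
seed-site creation/destruction in 3′-UTR flanks, and compared across
species with two-sided Fisher exact tests (biased if |Δlevel| ≥ 20 points
and p < 0.01).  Details and design decisions: `docs/methods.md`.

## Worked example

```bash
edscape simulate --seed 7 --config small.yaml --out demo/
edscape run-all --project demo/
```

with `small.yaml`:

```yaml
n_chroms: 1
chrom_length: 30000
n_genes: 4
n_sites: 60
n_het_snps: 10
rna_depth: 30
dna_depth: 30
n_regions: 2
samples_per_region: 2
```

prints (to stderr):

```
[edscape] simulated 60 sites into demo/
[edscape] hyperedit: recovered 153 reads
[edscape] call: 48 master sites
[edscape] stats written
[edscape] specificity written
[edscape] run-all complete
```

Reading the numbers: the generator planted 60 A-to-I sites (most at low
levels drawn from Beta(1,9), so some fall below the 3-read/5% evidence
floor at 30×) plus 10 heterozygous SNPs; 153 hyper-edited reads that were
diverted to the unmapped pool were recovered by transformed realignment;
round-1 calling then identified 48 sites that clear all four filters in at
least two samples — het-SNP positions are rejected by the DNA homozygosity
filter.  `demo/` now contains `master_sites.tsv` (1-based site list with
mismatch type, annotation and recoding notation), `quant.tsv` (per-sample
counts and levels), per-region `editing_R*.bedGraph` browser tracks,
`specificity.tsv`, a flanking-context table, and `manifest.json` with
checksums; re-running `run-all` skips completed stages.

The same pipeline is available as a library:

```python
from edscape import pipeline, simdata

result = pipeline.run_pipeline(simdata.SimConfig(rng_seed=1))
print(len(result.master))            # called sites
print(result.region_matrix.level)    # site x region editing levels
```

## Layout

| Module | Role |
| --- | --- |
| `edscape.simdata` | synthetic genome, truth set, DNA/RNA read simulation |
| `edscape.genome` | genome bundle: FASTA/GTF/BED containers and IO |
| `edscape.samio` | SAM/FASTQ IO, dedup, filtered pileups, seed-and-extend aligner |
| `edscape.hypered` | hyper-edited read recovery by A→G-transformed realignment |
| `edscape.caller` | two-round editing-site identification and quantification |
| `edscape.annot` | genic/repeat/recoding annotation, flanking-context statistics |
| `edscape.stats` | pooling, overall editing, size factors, clustering, PCA, rank tests |
| `edscape.specificity` | region-enriched / group-enriched / enhanced classification |
| `edscape.mirna` | miRNA seed-site creation/destruction in 3′-UTR flanks |
| `edscape.xspecies` | conserved-site Fisher tests and bias classification |
| `edscape.cli` / `edscape.pipeline` | subcommands, manifests, stage orchestration |
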