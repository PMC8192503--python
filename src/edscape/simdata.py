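"""Synthetic genome, truth set, and read simulation for A-to-I editing.

The generator emulates the input side of a brain editing survey at desk
scale: a toy genome with single-transcript gene models and diverged
SINE-like repeat copies; planted A-to-I sites whose per-region levels are
mostly low (repeat/intron classes) with a minority of highly edited
recoding sites; heterozygous A/G SNPs as confounders; strand-specific RNA
reads with per-base qualities, sequencing errors and PCR duplicates; and a
small fraction of hyper-edited molecules that are emitted to an unmapped
FASTQ instead of the alignment, to be recovered by transformed realignment.

All randomness flows from a single ``rng_seed``; outputs are byte-identical
for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .genome import (
    A,
    C,
    G,
    T,
    GeneModel,
    GenomeBundle,
    RepeatInterval,
    array_to_seq,
    revcomp_array,
    seq_to_array,
)
from .samio import FastqRead, ReadBlock, write_fastq, write_sam

SITE_CLASSES = ("repeat", "intron", "CDS-recoding", "CDS-synonymous", "UTR3", "UTR5")

# SINE/tRNA (PRE) subfamilies with frequencies mirroring their relative
# abundance among edited repeats
REPEAT_SUBFAMILIES = (
    ("SINE/tRNA:Pre0_SS", 0.60),
    ("SINE/tRNA:PRE1f", 0.15),
    ("SINE/tRNA:PRE1f2", 0.10),
    ("SINE/tRNA:PRE1g", 0.08),
    ("SINE/tRNA:PRE1e", 0.07),
)


class SizingError(ValueError):
    """Configuration does not fit in the requested genome."""


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults describe the standard fixture: two 200-kb chromosomes, twelve
    strand-specific RNA libraries (four animals x three pooling regions) at
    60x, DNA at 60x per animal, 500 planted sites, 50 heterozygous SNPs,
    0.1% base error.
    """

    rng_seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 200_000
    n_genes: int = 20
    exons_per_gene: int = 3
    repeat_fraction: float = 0.25
    n_sites: int = 500
    n_regions: int = 3
    samples_per_region: int = 4
    n_het_snps: int = 50
    read_length: int = 100
    rna_depth: float = 60.0
    dna_depth: float = 60.0
    base_error_rate: float = 0.001
    low_quality_fraction: float = 0.05  # fraction of bases below Q30
    duplicate_rate: float = 0.05
    hyper_read_fraction: float = 0.005
    # level model: per-class Beta(a, b) for the shared across-region level
    level_model: dict = field(
        default_factory=lambda: {
            "repeat": (1.0, 9.0),
            "intron": (1.0, 9.0),
            "UTR3": (1.0, 6.0),
            "UTR5": (1.0, 6.0),
            "CDS-recoding": (2.0, 2.0),
            "CDS-synonymous": (2.0, 2.0),
        }
    )
    # fraction of recoding sites edited near-completely ("Q/R-like")
    cds_high_fraction: float = 0.3
    site_class_weights: dict = field(
        default_factory=lambda: {
            "repeat": 0.60,
            "intron": 0.20,
            "UTR3": 0.08,
            "UTR5": 0.03,
            "CDS-recoding": 0.06,
            "CDS-synonymous": 0.03,
        }
    )
    # sites boosted in one region (0.5) over the rest (0.05)
    n_region_enriched: int = 40
    repeat_unit_length: int = 260
    repeat_divergence: float = 0.10
    # ADAR-like context bias: selection weight multipliers for a G at +1 / -1
    context_g_plus1_weight: float = 2.0
    context_g_minus1_weight: float = 0.5
    exon_length: int = 300
    intron_length: int = 700
    hyper_min_edit_prob: float = 0.2
    hyper_max_edit_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "repeat_fraction",
            "base_error_rate",
            "low_quality_fraction",
            "duplicate_rate",
            "hyper_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "n_chroms",
            "chrom_length",
            "n_genes",
            "exons_per_gene",
            "n_sites",
            "n_regions",
            "samples_per_region",
            "n_het_snps",
            "read_length",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.chrom_length < 10 * self.read_length:
            raise ValueError("chrom_length must be at least 10 x read_length")

    # ---- sample bookkeeping: sample R{r}A{a} is animal a in region r
    @property
    def regions(self) -> list[str]:
        return [f"R{r}" for r in range(self.n_regions)]

    @property
    def animals(self) -> list[str]:
        return [f"A{a}" for a in range(self.samples_per_region)]

    @property
    def samples(self) -> list[str]:
        return [f"{reg}{an}" for reg in self.regions for an in self.animals]

    def sample_region(self, sample: str) -> str:
        return sample.split("A")[0]

    def sample_animal(self, sample: str) -> str:
        return "A" + sample.split("A")[1]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class TruthSite:
    chrom: str
    pos: int  # 0-based
    strand: str
    site_class: str
    levels: np.ndarray  # per-region true level, ordered as config.regions

    def level_in(self, region_index: int) -> float:
        return float(self.levels[region_index])


@dataclass
class TruthSet:
    """Ground-truth ledger: planted sites, het SNPs, hyper-edited read ids."""

    sites: list[TruthSite]
    het_snps: list[tuple[str, int, str, str]]  # chrom, pos0, ref, alt
    regions: list[str]
    hyper_read_ids: set[str] = field(default_factory=set)

    def site_positions(self) -> set[tuple[str, int]]:
        return {(s.chrom, s.pos) for s in self.sites}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "chrom\tpos\tstrand\tclass\t"
                + "\t".join(f"level_{r}" for r in self.regions)
                + "\n"
            )
            for s in self.sites:
                levels = "\t".join(f"{v:.6g}" for v in s.levels)
                fh.write(f"{s.chrom}\t{s.pos + 1}\t{s.strand}\t{s.site_class}\t{levels}\n")

    def snps_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tref\talt\n")
            for chrom, pos, ref, alt in self.het_snps:
                fh.write(f"{chrom}\t{pos + 1}\t{ref}\t{alt}\n")


# ----------------------------------------------------------------- genome
def generate_reference(config: SimConfig) -> GenomeBundle:
    """Generate the toy genome: random sequence, gene models, repeat tiles.

    Genes are laid out left to right with random gaps; each transcript has
    non-overlapping exons, a CDS of length divisible by 3 starting with ATG,
    and terminal UTRs.  Repeat copies are diverged instances of per-subfamily
    consensus sequences, written into intergenic/intronic sequence so exons
    stay repeat-free.
    """
    rng = np.random.default_rng(config.rng_seed)
    bases = np.array([A, C, G, T], dtype=np.uint8)
    seqs = {
        f"chr{i + 1}": bases[rng.integers(0, 4, size=config.chrom_length)]
        for i in range(config.n_chroms)
    }
    chroms = list(seqs)

    gene_span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    if per_chrom * (gene_span + 200) > config.chrom_length:
        raise SizingError(
            f"{config.n_genes} genes of span {gene_span} bp do not fit in "
            f"{config.n_chroms} x {config.chrom_length} bp"
        )
    genes: list[GeneModel] = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = min(per_chrom, config.n_genes - gi)
        slack = config.chrom_length - n_here * gene_span
        gaps = rng.multinomial(max(slack - 200, 0), np.ones(n_here + 1) / (n_here + 1))
        cursor = 100
        for j in range(n_here):
            cursor += int(gaps[j])
            start = cursor
            exons = []
            for e in range(config.exons_per_gene):
                s = start + e * (config.exon_length + config.intron_length)
                exons.append((s, s + config.exon_length))
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _build_transcript(f"gene{gi + 1}", chrom, strand, exons, rng, seqs)
            )
            cursor = exons[-1][1]
            gi += 1
    genes.sort(key=lambda g: (g.chrom, g.start))

    repeats = _tile_repeats(seqs, genes, config, rng)
    return GenomeBundle(seqs=seqs, genes=genes, repeats=repeats)


def _build_transcript(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: list[tuple[int, int]],
    rng: np.random.Generator,
    seqs: dict[str, np.ndarray],
) -> GeneModel:
    """Carve a CDS (multiple of 3, ATG start) and UTRs out of the exons."""
    total = sum(e - s for s, e in exons)
    utr5_len = int(rng.integers(60, 120))
    utr3_len = int(rng.integers(120, 240))
    cds_len = total - utr5_len - utr3_len
    cds_len -= cds_len % 3
    utr3_len = total - utr5_len - cds_len

    # walk exons in transcript order assigning utr5 | cds | utr3
    tx_exons = exons if strand == "+" else exons[::-1]
    segments = {"utr5": [], "cds": [], "utr3": []}
    remaining = {"utr5": utr5_len, "cds": cds_len, "utr3": utr3_len}
    order = ["utr5", "cds", "utr3"]
    seg_i = 0
    for s, e in tx_exons:
        length = e - s
        offset = 0
        while length > 0 and seg_i < 3:
            name = order[seg_i]
            take = min(length, remaining[name])
            if take == 0:
                seg_i += 1
                continue
            if strand == "+":
                segments[name].append((s + offset, s + offset + take))
            else:
                segments[name].append((e - offset - take, e - offset))
            offset += take
            length -= take
            remaining[name] -= take
            if remaining[name] == 0:
                seg_i += 1
    cds = sorted(segments["cds"])
    # force an ATG start codon on the coding strand
    arr = seqs[chrom]
    if strand == "+":
        arr[cds[0][0] : cds[0][0] + 3] = seq_to_array("ATG")
    else:
        arr[cds[-1][1] - 3 : cds[-1][1]] = revcomp_array(seq_to_array("ATG"))
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
        utr5=sorted(segments["utr5"]),
        utr3=sorted(segments["utr3"]),
    )


def _tile_repeats(
    seqs: dict[str, np.ndarray],
    genes: list[GeneModel],
    config: SimConfig,
    rng: np.random.Generator,
) -> list[RepeatInterval]:
    if config.repeat_fraction == 0:
        return []
    bases = np.array([A, C, G, T], dtype=np.uint8)
    unit = config.repeat_unit_length
    names = [n for n, _ in REPEAT_SUBFAMILIES]
    weights = np.array([w for _, w in REPEAT_SUBFAMILIES])
    consensus = {
        n: bases[rng.integers(0, 4, size=unit)] for n in names
    }
    exon_blocks: dict[str, list[tuple[int, int]]] = {c: [] for c in seqs}
    for g in genes:
        exon_blocks[g.chrom].extend(g.exons)
    repeats: list[RepeatInterval] = []
    for chrom, arr in seqs.items():
        length = len(arr)
        n_copies = int(config.repeat_fraction * length / unit)
        blocked = sorted(exon_blocks[chrom])
        occupied: list[tuple[int, int]] = list(blocked)
        placed = 0
        attempts = 0
        while placed < n_copies and attempts < n_copies * 50:
            attempts += 1
            start = int(rng.integers(0, length - unit))
            iv = (start, start + unit)
            if any(s < iv[1] and iv[0] < e for s, e in occupied):
                continue
            occupied.append(iv)
            name = names[rng.choice(len(names), p=weights / weights.sum())]
            copy = consensus[name].copy()
            div = np.flatnonzero(rng.random(unit) < config.repeat_divergence)
            copy[div] = bases[(TWOBIT_OF[copy[div]] + rng.integers(1, 4, len(div))) % 4]
            strand = "+" if rng.random() < 0.5 else "-"
            arr[start : start + unit] = copy if strand == "+" else revcomp_array(copy)
            repeats.append(RepeatInterval(chrom, start, start + unit, name, strand))
            placed += 1
    repeats.sort(key=lambda r: (r.chrom, r.start))
    return repeats


# base ASCII -> 2-bit (local copy to avoid import cycle churn)
TWOBIT_OF = np.zeros(256, dtype=np.int64)
TWOBIT_OF[C], TWOBIT_OF[G], TWOBIT_OF[T] = 1, 2, 3


# -------------------------------------------------------------- truth set
def plant_truth(bundle: GenomeBundle, config: SimConfig) -> TruthSet:
    """Plant editing sites, per-region levels, and heterozygous SNPs.

    Sites are placed on reference-A positions of their edited strand (the
    host-gene strand inside genes, '+' elsewhere).  Repeat-class sites are
    sampled a few per repeat copy so that they cluster within 100 bp, as
    editing does in inverted SINE pairs; candidate As are weighted by the
    ADAR-like neighbour preference (G depleted at -1, enriched at +1).
    """
    rng = np.random.default_rng(config.rng_seed + 1)
    pools = _candidate_pools(bundle)
    class_w = np.array([config.site_class_weights[k] for k in SITE_CLASSES], float)
    counts = rng.multinomial(config.n_sites, class_w / class_w.sum())
    quota = dict(zip(SITE_CLASSES, counts))

    sites: list[TruthSite] = []
    taken: set[tuple[str, int]] = set()
    for cls in SITE_CLASSES:
        need = int(quota[cls])
        if need == 0:
            continue
        pool = pools[cls]
        if len(pool) < need:
            raise SizingError(
                f"class {cls}: requested {need} sites but only {len(pool)} "
                "candidate A positions available"
            )
        if cls == "repeat":
            chosen = _sample_clustered(pool, need, rng, bundle, config, taken)
        else:
            chosen = _sample_weighted(pool, need, rng, bundle, config, taken)
        for chrom, pos, strand in chosen:
            levels = _draw_levels(cls, config, rng)
            sites.append(TruthSite(chrom, pos, strand, cls, levels))
            taken.add((chrom, pos))

    # region-enriched sites: boost one region on repeat-class sites
    repeat_sites = [s for s in sites if s.site_class == "repeat"]
    n_enriched = min(config.n_region_enriched, len(repeat_sites))
    if config.n_regions >= 2 and n_enriched:
        idx = rng.choice(len(repeat_sites), size=n_enriched, replace=False)
        for i in idx:
            target = int(rng.integers(0, config.n_regions))
            repeat_sites[i].levels = np.full(config.n_regions, 0.05)
            repeat_sites[i].levels[target] = 0.5

    # guarantee one near-fully edited recoding site in every region
    recoding = [s for s in sites if s.site_class == "CDS-recoding"]
    if recoding:
        recoding[0].levels = np.full(config.n_regions, 0.995)

    het_snps = _plant_het_snps(bundle, config, rng, taken)
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return TruthSet(sites=sites, het_snps=het_snps, regions=config.regions)


def _host_strand(bundle: GenomeBundle, chrom: str, pos: int) -> str:
    hits = [g for g in bundle.genes if g.chrom == chrom and g.contains(pos)]
    return hits[0].strand if len(hits) == 1 else "+"


def _edited_A_positions(
    bundle: GenomeBundle, chrom: str, intervals: list[tuple[int, int]], strand: str
) -> np.ndarray:
    """Positions in intervals where the edited-strand base is A."""
    want = A if strand == "+" else T
    arr = bundle.seqs[chrom]
    out = []
    for s, e in intervals:
        rel = np.flatnonzero(arr[s:e] == want)
        out.append(rel + s)
    return np.concatenate(out) if out else np.zeros(0, dtype=np.int64)


def _candidate_pools(bundle: GenomeBundle) -> dict[str, list[tuple[str, int, str]]]:
    pools: dict[str, list[tuple[str, int, str]]] = {k: [] for k in SITE_CLASSES}
    repeat_span: dict[str, list[tuple[int, int]]] = {}
    for r in bundle.repeats:
        repeat_span.setdefault(r.chrom, []).append((r.start, r.end))

    for r in bundle.repeats:
        strand = _host_strand(bundle, r.chrom, (r.start + r.end) // 2)
        for pos in _edited_A_positions(bundle, r.chrom, [(r.start, r.end)], strand):
            pools["repeat"].append((r.chrom, int(pos), strand))

    def in_repeat(chrom: str, pos: int) -> bool:
        return any(s <= pos < e for s, e in repeat_span.get(chrom, []))

    for g in bundle.genes:
        for pos in _edited_A_positions(bundle, g.chrom, g.introns(), g.strand):
            if not in_repeat(g.chrom, int(pos)):
                pools["intron"].append((g.chrom, int(pos), g.strand))
        for name, ivs in (("UTR3", g.utr3), ("UTR5", g.utr5)):
            for pos in _edited_A_positions(bundle, g.chrom, ivs, g.strand):
                pools[name].append((g.chrom, int(pos), g.strand))
        for pos in _edited_A_positions(bundle, g.chrom, g.cds, g.strand):
            # protect the start codon so the forced ATG stays intact
            off = g.cds_offset_of(int(pos))
            if off is None or off < 3:
                continue
            eff = recoding_effect_of(bundle, g, int(pos))
            cls = "CDS-synonymous" if eff.is_synonymous else "CDS-recoding"
            pools[cls].append((g.chrom, int(pos), g.strand))
    return pools


def recoding_effect_of(bundle: GenomeBundle, gene: GeneModel, pos: int):
    from .annot import recoding_effect

    return recoding_effect(bundle, gene, pos)


def _context_weights(
    bundle: GenomeBundle, cands: list[tuple[str, int, str]], config: SimConfig
) -> np.ndarray:
    w = np.ones(len(cands))
    for i, (chrom, pos, strand) in enumerate(cands):
        arr = bundle.seqs[chrom]
        if pos - 1 < 0 or pos + 1 >= len(arr):
            continue
        if strand == "+":
            minus1, plus1 = chr(arr[pos - 1]), chr(arr[pos + 1])
        else:
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            minus1, plus1 = comp[chr(arr[pos + 1])], comp[chr(arr[pos - 1])]
        if plus1 == "G":
            w[i] *= config.context_g_plus1_weight
        if minus1 == "G":
            w[i] *= config.context_g_minus1_weight
    return w


def _sample_weighted(pool, need, rng, bundle, config, taken):
    cands = [c for c in pool if (c[0], c[1]) not in taken]
    w = _context_weights(bundle, cands, config)
    idx = rng.choice(len(cands), size=need, replace=False, p=w / w.sum())
    return [cands[i] for i in idx]


def _sample_clustered(pool, need, rng, bundle, config, taken):
    """Sample repeat sites a few per copy so clusters (>=3 in 100 bp) form."""
    by_copy: dict[tuple[str, int], list[tuple[str, int, str]]] = {}
    for chrom, pos, strand in pool:
        if (chrom, pos) in taken:
            continue
        by_copy.setdefault((chrom, pos // config.repeat_unit_length), []).append(
            (chrom, pos, strand)
        )
    copies = sorted(by_copy)
    chosen: list[tuple[str, int, str]] = []
    order = rng.permutation(len(copies))
    for ci in order:
        if len(chosen) >= need:
            break
        cands = by_copy[copies[ci]]
        k = min(int(rng.integers(3, 7)), len(cands), need - len(chosen))
        if k == 0:
            continue
        w = _context_weights(bundle, cands, config)
        idx = rng.choice(len(cands), size=k, replace=False, p=w / w.sum())
        # cluster within the copy: restrict to a 100-bp anchor window
        anchor = cands[int(idx[0])][1]
        near = [
            j
            for j in range(len(cands))
            if abs(cands[j][1] - anchor) <= 50
        ]
        if len(near) >= k:
            wn = w[near]
            idx = rng.choice(near, size=k, replace=False, p=wn / wn.sum())
        chosen.extend(cands[int(j)] for j in idx)
    if len(chosen) < need:
        raise SizingError("not enough repeat A positions for requested sites")
    return chosen[:need]


def _draw_levels(cls: str, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if cls == "CDS-recoding" and rng.random() < config.cds_high_fraction:
        base = float(rng.uniform(0.99, 1.0))
    else:
        a, b = config.level_model[cls]
        base = float(rng.beta(a, b))
    return np.full(config.n_regions, base)


def _plant_het_snps(bundle, config, rng, taken):
    """Heterozygous A/G SNPs at genic A positions, disjoint from sites."""
    cands: list[tuple[str, int]] = []
    for g in bundle.genes:
        for pos in _edited_A_positions(
            bundle, g.chrom, [(g.start, g.end)], "+"
        ):
            if (g.chrom, int(pos)) not in taken:
                cands.append((g.chrom, int(pos)))
    if config.n_het_snps == 0:
        return []
    if len(cands) < config.n_het_snps:
        raise SizingError("not enough A positions for requested het SNPs")
    idx = rng.choice(len(cands), size=config.n_het_snps, replace=False)
    snps = [(cands[i][0], cands[i][1], "A", "G") for i in sorted(idx)]
    return snps


# ----------------------------------------------------------------- reads
@dataclass
class SimReads:
    """Simulated alignments and unmapped hyper-edited reads."""

    rna: dict[str, list[ReadBlock]]  # sample -> one block per chrom
    dna: dict[str, list[ReadBlock]]  # animal -> one block per chrom
    unmapped: dict[str, list[FastqRead]]  # sample -> hyper-edited reads
    config: SimConfig

    def rna_read_counts(self) -> dict[str, int]:
        return {s: sum(b.n for b in blocks) for s, blocks in self.rna.items()}


def simulate_reads(
    bundle: GenomeBundle, truth: TruthSet, config: SimConfig
) -> SimReads:
    """Simulate DNA reads per animal and strand-specific RNA reads per sample.

    RNA coverage is uniform over the genome (ribo-depleted total RNA over a
    toy genome, so intronic and repeat sites are observable); the read
    strand is the host gene's strand inside genes and '+' elsewhere.  A read
    covering a planted site carries the edited base with probability equal
    to the site's true level in the sample's region, independently per
    read.  Designated hyper-edited reads instead have every A of their
    transcript sense edited with a per-molecule probability of at least
    ``hyper_min_edit_prob`` and are diverted to the unmapped FASTQ.
    """
    rng = np.random.default_rng(config.rng_seed + 2)
    chroms = list(bundle.seqs)
    gene_lookup = {c: _gene_strand_arrays(bundle, c) for c in chroms}
    sites_by_chrom: dict[str, list[tuple[int, str, np.ndarray]]] = {c: [] for c in chroms}
    for s in truth.sites:
        sites_by_chrom[s.chrom].append((s.pos, s.strand, s.levels))
    snps_by_chrom: dict[str, list[tuple[int, str]]] = {c: [] for c in chroms}
    for chrom, pos, _ref, alt in truth.het_snps:
        snps_by_chrom[chrom].append((pos, alt))

    rna: dict[str, list[ReadBlock]] = {}
    unmapped: dict[str, list[FastqRead]] = {}
    region_index = {r: i for i, r in enumerate(config.regions)}
    for sample in config.samples:
        ri = region_index[config.sample_region(sample)]
        blocks = []
        fastq: list[FastqRead] = []
        for chrom in chroms:
            block, hyper = _simulate_rna_chrom(
                bundle, chrom, sample, ri, sites_by_chrom[chrom],
                snps_by_chrom[chrom], gene_lookup[chrom], config, rng, truth,
            )
            blocks.append(block)
            fastq.extend(hyper)
        rna[sample] = blocks
        unmapped[sample] = fastq

    dna: dict[str, list[ReadBlock]] = {}
    for animal in config.animals:
        dna[animal] = [
            _simulate_dna_chrom(bundle, chrom, animal, snps_by_chrom[chrom], config, rng)
            for chrom in chroms
        ]
    return SimReads(rna=rna, dna=dna, unmapped=unmapped, config=config)


def _gene_strand_arrays(bundle: GenomeBundle, chrom: str):
    genes = [g for g in bundle.genes if g.chrom == chrom]
    starts = np.array([g.start for g in genes], dtype=np.int64)
    ends = np.array([g.end for g in genes], dtype=np.int64)
    strands = np.array([1 if g.strand == "-" else 0 for g in genes], dtype=np.uint8)
    return starts, ends, strands


def _read_strands(midpoints: np.ndarray, lookup) -> np.ndarray:
    """Strand per read: host gene strand if the midpoint is genic, else '+'."""
    starts, ends, strands = lookup
    out = np.zeros(len(midpoints), dtype=np.uint8)
    if len(starts) == 0:
        return out
    gi = np.searchsorted(starts, midpoints, side="right") - 1
    valid = (gi >= 0) & (midpoints < ends[np.clip(gi, 0, None)])
    out[valid] = strands[gi[valid]]
    return out


def _random_quals(rng, shape, config) -> np.ndarray:
    low = rng.random(shape) < config.low_quality_fraction
    quals = rng.integers(30, 42, size=shape).astype(np.uint8)
    quals[low] = rng.integers(2, 30, size=int(low.sum())).astype(np.uint8)
    return quals


def _apply_errors(seqs, rng, rate) -> None:
    if rate <= 0:
        return
    err = rng.random(seqs.shape) < rate
    n = int(err.sum())
    if n == 0:
        return
    codes = TWOBIT_OF[seqs[err]]
    new = (codes + rng.integers(1, 4, size=n)) % 4
    seqs[err] = np.array([A, C, G, T], dtype=np.uint8)[new]


def _apply_het_snps(seqs, starts, snps, rng, L) -> None:
    for pos, alt in snps:
        idx = np.flatnonzero((starts > pos - L) & (starts <= pos))
        if len(idx) == 0:
            continue
        carry = idx[rng.random(len(idx)) < 0.5]
        seqs[carry, pos - starts[carry]] = ord(alt)


def _simulate_rna_chrom(
    bundle, chrom, sample, region_index, sites, snps, lookup, config, rng, truth
):
    L = config.read_length
    glen = len(bundle.seqs[chrom])
    n_reads = int(round(config.rna_depth * glen / L))
    starts = np.sort(rng.integers(0, glen - L + 1, size=n_reads).astype(np.int64))
    seqs = bundle.seqs[chrom][starts[:, None] + np.arange(L)[None, :]].copy()
    strands = _read_strands(starts + L // 2, lookup)

    # designate hyper-edited molecules (must have enough As to hyper-edit)
    hyper_mask = rng.random(n_reads) < config.hyper_read_fraction
    sense_a = np.where(strands == 0, (seqs == A).sum(axis=1), (seqs == T).sum(axis=1))
    hyper_mask &= sense_a >= 10

    _apply_het_snps(seqs, starts, snps, rng, L)

    # per-site independent editing of non-hyper reads
    for pos, strand, levels in sites:
        level = float(levels[region_index])
        if level <= 0:
            continue
        idx = np.flatnonzero((starts > pos - L) & (starts <= pos))
        if len(idx) == 0:
            continue
        want = 0 if strand == "+" else 1
        idx = idx[(strands[idx] == want) & ~hyper_mask[idx]]
        edit = idx[rng.random(len(idx)) < level]
        cols = pos - starts[edit]
        seqs[edit, cols] = G if strand == "+" else C

    # hyper-edit designated molecules: every sense A with prob p >= 0.2
    hyper_idx = np.flatnonzero(hyper_mask)
    for i in hyper_idx:
        p = float(rng.uniform(config.hyper_min_edit_prob, config.hyper_max_edit_prob))
        if strands[i] == 0:
            a_cols = np.flatnonzero(seqs[i] == A)
            sub = G
        else:
            a_cols = np.flatnonzero(seqs[i] == T)
            sub = C
        edit = a_cols[rng.random(len(a_cols)) < p]
        if len(edit) < 5:  # enforce genuinely hyper-edited molecules
            edit = a_cols[rng.choice(len(a_cols), size=5, replace=False)]
        seqs[i, edit] = sub

    _apply_errors(seqs, rng, config.base_error_rate)
    quals = _random_quals(rng, seqs.shape, config)
    strand_char = np.where(strands == 0, "+", "-")
    ids = np.array(
        [
            f"{sample}:{chrom}:{starts[i] + 1}:{strand_char[i]}:{i}"
            for i in range(n_reads)
        ]
    )

    # split off hyper reads -> unmapped FASTQ (read-sequenced orientation)
    fastq = []
    for i in hyper_idx:
        if strands[i] == 0:
            seq, q = array_to_seq(seqs[i]), quals[i]
        else:
            seq, q = array_to_seq(revcomp_array(seqs[i])), quals[i][::-1]
        fastq.append(FastqRead(read_id=str(ids[i]), sequence=seq, qualities=q))
        truth.hyper_read_ids.add(str(ids[i]))
    keep = ~hyper_mask
    block = ReadBlock(
        sample_id=sample,
        chrom=chrom,
        starts=starts[keep],
        strands=strands[keep],
        seqs=seqs[keep],
        quals=quals[keep],
        ids=ids[keep],
    )
    block = _append_duplicates(block, rng, config)
    return block, fastq


def _simulate_dna_chrom(bundle, chrom, animal, snps, config, rng) -> ReadBlock:
    L = config.read_length
    glen = len(bundle.seqs[chrom])
    n_reads = int(round(config.dna_depth * glen / L))
    starts = np.sort(rng.integers(0, glen - L + 1, size=n_reads).astype(np.int64))
    seqs = bundle.seqs[chrom][starts[:, None] + np.arange(L)[None, :]].copy()
    strands = (rng.random(n_reads) < 0.5).astype(np.uint8)
    _apply_het_snps(seqs, starts, snps, rng, L)
    _apply_errors(seqs, rng, config.base_error_rate)
    quals = _random_quals(rng, seqs.shape, config)
    ids = np.array(
        [
            f"{animal}:dna:{chrom}:{starts[i] + 1}:{'-' if strands[i] else '+'}:{i}"
            for i in range(n_reads)
        ]
    )
    block = ReadBlock(
        sample_id=animal, chrom=chrom, starts=starts, strands=strands,
        seqs=seqs, quals=quals, ids=ids,
    )
    return _append_duplicates(block, rng, config)


def _append_duplicates(block: ReadBlock, rng, config: SimConfig) -> ReadBlock:
    n_dup = int(round(config.duplicate_rate * block.n))
    if n_dup == 0:
        return block
    src = rng.choice(block.n, size=n_dup, replace=False)
    dup = block.take(np.sort(src))
    dup_ids = np.array([f"{rid}/dup" for rid in dup.ids])
    merged = ReadBlock(
        sample_id=block.sample_id,
        chrom=block.chrom,
        starts=np.concatenate([block.starts, dup.starts]),
        strands=np.concatenate([block.strands, dup.strands]),
        seqs=np.vstack([block.seqs, dup.seqs]),
        quals=np.vstack([block.quals, dup.quals]),
        ids=np.concatenate([block.ids, dup_ids]),
        mapq=block.mapq,
    )
    return merged.sort()


# ------------------------------------------------------------------ output
def write_outputs(
    bundle: GenomeBundle,
    truth: TruthSet,
    reads: SimReads,
    outdir: str | Path,
) -> dict[str, str]:
    """Write FASTA/GTF/BED, truth TSVs, per-animal DNA SAM, per-sample RNA
    SAM and unmapped FASTQ, plus a JSON config echo.  Returns a path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    chrom_lengths = bundle.chrom_lengths

    def record(key: str, path: Path) -> Path:
        paths[key] = str(path)
        return path

    bundle.write_fasta(record("genome", outdir / "genome.fa"))
    bundle.write_gtf(record("genes", outdir / "genes.gtf"))
    bundle.write_repeat_bed(record("repeats", outdir / "repeats.bed"))
    truth.to_tsv(record("truth_sites", outdir / "truth_sites.tsv"))
    truth.snps_to_tsv(record("truth_snps", outdir / "truth_het_snps.tsv"))
    with open(record("config", outdir / "sim_config.json"), "w") as fh:
        fh.write(reads.config.to_json() + "\n")
    with open(record("hyper_reads", outdir / "truth_hyper_reads.txt"), "w") as fh:
        for rid in sorted(truth.hyper_read_ids):
            fh.write(rid + "\n")
    for sample, blocks in reads.rna.items():
        write_sam(blocks, record(f"rna:{sample}", outdir / f"rna_{sample}.sam"), chrom_lengths)
        write_fastq(
            reads.unmapped[sample],
            record(f"unmapped:{sample}", outdir / f"unmapped_{sample}.fastq"),
        )
    for animal, blocks in reads.dna.items():
        write_sam(blocks, record(f"dna:{animal}", outdir / f"dna_{animal}.sam"), chrom_lengths)
    return paths
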