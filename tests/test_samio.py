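import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from edscape import samio
from edscape.genome import revcomp, seq_to_array


def _read(read_id, start, seq, strand="+", qual=40, chrom="chr1", sample="s"):
    return samio.ReadAlignment(
        read_id=read_id, sample_id=sample, chrom=chrom, start=start,
        strand=strand, sequence=seq,
        qualities=np.full(len(seq), qual, dtype=np.uint8),
    )


# ------------------------------------------------------------------ SAM IO
def test_sam_round_trip_is_byte_stable(tmp_path, small_world):
    bundle, _, reads = small_world
    sample = next(iter(reads.rna))
    path1, path2 = tmp_path / "a.sam", tmp_path / "b.sam"
    samio.write_sam(reads.rna[sample], path1, bundle.chrom_lengths)
    alignments = samio.read_sam(path1, sample)
    samio.write_sam(alignments, path2, bundle.chrom_lengths)
    assert path1.read_bytes() == path2.read_bytes()
    assert len(alignments) == sum(b.n for b in reads.rna[sample])


def test_empty_sam_with_headers_gives_empty_list(tmp_path):
    path = tmp_path / "empty.sam"
    path.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
    assert samio.read_sam(path) == []


def test_malformed_record_rejected_with_record_number(tmp_path):
    path = tmp_path / "bad.sam"
    path.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t10\t60\t4M\t*\t0\t0\tACGT\tIIII\n"
        "r2\t0\tchr1\t20\t60\t4M\t*\t0\t0\tACGT\tII\n"  # qual/seq mismatch
    )
    with pytest.raises(samio.SamFormatError, match="record 2"):
        samio.read_sam(path)


def test_fastq_round_trip(tmp_path):
    reads = [
        samio.FastqRead("r1", "ACGTACGT", np.arange(8, dtype=np.uint8) + 30),
        samio.FastqRead("r2", "TTTTAAAA", np.full(8, 2, dtype=np.uint8)),
    ]
    path = tmp_path / "x.fastq"
    samio.write_fastq(reads, path)
    back = samio.read_fastq(path)
    assert [(r.read_id, r.sequence) for r in back] == [
        (r.read_id, r.sequence) for r in reads
    ]
    assert all(np.array_equal(a.qualities, b.qualities) for a, b in zip(back, reads))


# --------------------------------------------------------------- dedup
def test_duplicates_collapse_to_highest_quality_then_lexicographic_id():
    a = _read("rB", 10, "ACGTACGT", qual=30)
    b = _read("rA", 10, "ACGTACGT", qual=30)
    c = _read("rC", 10, "ACGTACGT", qual=35)
    kept = samio.remove_duplicates([a, b, c])
    assert [r.read_id for r in kept] == ["rC"]
    # pure tie: lexicographically smallest id survives
    kept = samio.remove_duplicates([a, b])
    assert [r.read_id for r in kept] == ["rA"]


def test_dedup_distinct_reads_untouched_and_idempotent():
    reads = [_read(f"r{i}", 10 * i, "ACGTACGT") for i in range(5)]
    once = samio.remove_duplicates(reads)
    assert once == reads
    assert samio.remove_duplicates(once) == once


def test_dedup_removes_exactly_planted_duplicates(small_world):
    # the generator appends '/dup' copies; dedup must remove one read per
    # duplicated (start, strand) key
    _, _, reads = small_world
    sample = next(iter(reads.rna))
    for block in reads.rna[sample]:
        out = samio.remove_duplicates_block(block)
        keys = {(int(s), int(t)) for s, t in zip(block.starts, block.strands)}
        assert out.n == len(keys)


@settings(deadline=None, derandomize=True, max_examples=25)
@given(st.lists(st.tuples(st.integers(0, 30), st.booleans(), st.integers(30, 41)),
                min_size=1, max_size=40))
def test_block_dedup_matches_list_dedup(items):
    reads = [
        _read(f"r{i}", start, "ACGTACGTAC", "-" if rev else "+", qual)
        for i, (start, rev, qual) in enumerate(items)
    ]
    expected = {
        (r.chrom, r.start, r.strand, r.read_id)
        for r in samio.remove_duplicates(reads)
    }
    block = samio.blocks_from_alignments(reads, "s")[0]
    out = samio.remove_duplicates_block(block)
    got = {
        ("chr1", int(out.starts[i]), "-" if out.strands[i] else "+", str(out.ids[i]))
        for i in range(out.n)
    }
    assert got == expected


# --------------------------------------------------------------- pileup
def test_end_clipping_covers_central_window_only():
    read = _read("r1", 100, "A" * 20, qual=40)
    pileup = samio.build_pileup([read], {"chr1": 200}, layer="RNA")
    cov = pileup.counts("s", "RNA", "chr1").sum(axis=0)
    covered = np.flatnonzero(cov)
    # 20-bp read: after clipping 6 from each end, offsets 6..13 remain
    assert covered.tolist() == list(range(106, 114))


def test_quality_29_base_excluded_at_unclipped_offset():
    quals = np.full(20, 40, dtype=np.uint8)
    quals[10] = 29
    read = samio.ReadAlignment("r1", "s", "chr1", 0, "+", "A" * 20, quals)
    pileup = samio.build_pileup([read], {"chr1": 100}, layer="RNA")
    cov = pileup.counts("s", "RNA", "chr1").sum(axis=0)
    assert cov[10] == 0 and cov[9] == 1 and cov[11] == 1


def test_dna_layer_filters_quality_but_not_ends():
    quals = np.full(20, 40, dtype=np.uint8)
    quals[0] = 10
    read = samio.ReadAlignment("r1", "s", "chr1", 0, "+", "C" * 20, quals)
    pileup = samio.build_pileup([read], {"chr1": 100}, layer="DNA", end_clip=0)
    cov = pileup.counts("s", "DNA", "chr1").sum(axis=0)
    assert cov[0] == 0 and cov[1:20].sum() == 19


def test_pileup_matches_per_base_recount(rng):
    # brute-force oracle: apply the quality/clip rules base by base
    L, n, glen = 30, 50, 500
    reads = []
    for i in range(n):
        start = int(rng.integers(0, glen - L))
        seq = "".join(rng.choice(list("ACGT"), L))
        quals = rng.integers(2, 42, L).astype(np.uint8)
        reads.append(samio.ReadAlignment(f"r{i}", "s", "chr1", start,
                                         "+", seq, quals))
    pileup = samio.build_pileup(reads, {"chr1": glen}, layer="RNA",
                                quality_min=30, end_clip=6)
    expected = np.zeros((4, glen), dtype=int)
    for r in reads:
        for off, (base, q) in enumerate(zip(r.sequence, r.qualities)):
            if q >= 30 and 6 <= off < L - 6:
                expected["ACGT".index(base), r.start + off] += 1
    assert np.array_equal(pileup.counts("s", "RNA", "chr1"), expected)


def test_pileup_coverage_bounded_by_overlapping_reads(small_world):
    bundle, _, reads = small_world
    sample = next(iter(reads.rna))
    block = reads.rna[sample][0]
    pileup = samio.Pileup(bundle.chrom_lengths)
    pileup.add_block(block, "RNA")
    cov = pileup.counts(sample, "RNA", block.chrom).sum(axis=0)
    for pos in np.flatnonzero(cov)[::500]:
        assert cov[pos] <= len(block.overlapping(int(pos)))


# ------------------------------------------------- seed-and-extend aligner
def test_unique_read_aligns_uniquely_with_zero_mismatches(rng):
    genome = {"chr1": seq_to_array("".join(rng.choice(list("ACGT"), 3000)))}
    read = genome["chr1"][1000:1100].tobytes().decode()
    hits = samio.seed_extend_align(read, genome)
    assert len(hits) == 1
    assert (hits[0].chrom, hits[0].start, hits[0].strand) == ("chr1", 1000, "+")
    assert hits[0].mismatch_count == 0 and hits[0].is_unique


def test_reverse_strand_read_found(rng):
    genome = {"chr1": seq_to_array("".join(rng.choice(list("ACGT"), 2000)))}
    read = revcomp(genome["chr1"][500:600].tobytes().decode())
    hits = samio.seed_extend_align(read, genome)
    assert hits[0].strand == "-" and hits[0].start == 500 and hits[0].is_unique


def test_duplicated_sequence_is_not_unique(rng):
    base = "".join(rng.choice(list("ACGT"), 2000))
    insert = "".join(rng.choice(list("ACGT"), 120))
    genome = {"chr1": seq_to_array(base[:500] + insert + base[500:1000]
                                   + insert + base[1000:])}
    hits = samio.seed_extend_align(insert, genome)
    best = [h for h in hits if h.mismatch_count == 0]
    assert len(best) >= 2
    assert not hits[0].is_unique


def test_read_shorter_than_seed_raises():
    genome = {"chr1": seq_to_array("ACGT" * 100)}
    with pytest.raises(ValueError, match="shorter than seed"):
        samio.seed_extend_align("ACGTACGT", genome, k=16)


def test_hits_match_exhaustive_scan_oracle(rng):
    # oracle: sliding-window mismatch count on both strands of a 5-kb genome;
    # reads carry <= 4 mutations so an exact 16-mer seed always survives and
    # the seed-based and exhaustive definitions provably coincide
    genome = {"chr1": seq_to_array("".join(rng.choice(list("ACGT"), 5000)))}
    arr = genome["chr1"]
    for _ in range(10):
        start = int(rng.integers(0, 4900))
        read = list(arr[start : start + 100].tobytes().decode())
        for pos in rng.choice(100, size=int(rng.integers(0, 5)), replace=False):
            read[pos] = rng.choice([b for b in "ACGT" if b != read[pos]])
        read = "".join(read)
        got = {
            (h.start, h.strand, h.mismatch_count)
            for h in samio.seed_extend_align(read, genome)
        }
        expected = set()
        fwd, rev = seq_to_array(read), seq_to_array(revcomp(read))
        for s in range(0, 4901):
            for strand, q in (("+", fwd), ("-", rev)):
                mm = int(np.count_nonzero(arr[s : s + 100] != q))
                if mm <= 10:
                    expected.add((s, strand, mm))
        assert got == expected


def test_aligner_recall_on_error_free_simulated_reads():
    from edscape import pipeline, simdata
    cfg = simdata.SimConfig(
        rng_seed=9, n_chroms=1, chrom_length=15_000, n_genes=2, n_sites=10,
        n_het_snps=0, rna_depth=1.0, dna_depth=0, n_regions=1,
        samples_per_region=1, base_error_rate=0.0, duplicate_rate=0.0,
        hyper_read_fraction=0.0,
    )
    bundle, truth, reads = pipeline.simulate(cfg)
    index = samio.GenomeIndex(bundle.seqs, 16)
    block = reads.rna[cfg.samples[0]][0]
    for i in range(0, block.n, 7):
        read = block.seqs[i].tobytes().decode()
        hits = samio.seed_extend_align(read, bundle.seqs, index=index)
        assert any(h.start == block.starts[i] for h in hits)
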