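"""miRNA seed-site alteration prediction for 3'-UTR editing sites.

A site's 13-nt mRNA-sense flank (6 nt each side) is scanned, once with the
genomic A and once with the edited G at the center, against the seeds of a
mature-miRNA catalogue.  A window matches a miRNA when it is the exact
Watson-Crick reverse complement of the seed (A-U/G-C only, no G.U wobble)
and covers the edited position — otherwise editing could not alter the
match.  A seed match present for A but not G is destroyed by editing; the
converse is created.

The default seed is positions 2-8 (7 nt); a literal 2-7 (6 nt) scheme is
selectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}
CENTER = 6  # index of the edited base in a 13-nt flank


class MirnaFormatError(ValueError):
    pass


@dataclass(frozen=True)
class MirnaHit:
    site_id: str
    mirna_id: str
    status: str  # destroyed | created | unchanged
    offset: int  # window start within the flank
    allele: str  # allele generating the match


def load_mirnas(path: str | Path) -> tuple[list[tuple[str, str]], list[str]]:
    """Load a miRBase-style mature FASTA.

    Sequences are uppercased with T normalised to U; records containing
    other characters are rejected and their ids returned as the second
    element.
    """
    mirnas: list[tuple[str, str]] = []
    rejected: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        if seq and all(b in "AUCG" for b in seq):
            mirnas.append((rec.id, seq))
        else:
            rejected.append(rec.id)
    return mirnas, rejected


def seed_of(mirna_sequence: str, scheme: str = "2-8") -> str:
    """Seed substring of a mature miRNA: positions 2-8 (7 nt, default) or
    the literal 2-7 (6 nt) scheme."""
    if scheme == "2-8":
        lo, hi = 1, 8
    elif scheme == "2-7":
        lo, hi = 1, 7
    else:
        raise ValueError(f"unknown seed scheme {scheme!r}")
    if len(mirna_sequence) < hi:
        raise MirnaFormatError(
            f"miRNA of length {len(mirna_sequence)} too short for seed {scheme}"
        )
    return mirna_sequence[lo:hi]


def _rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _revcomp_rna(seq: str) -> str:
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(seq))


def scan_site(
    flank13: str,
    allele: str,
    seeds: dict[str, str],
) -> set[tuple[str, int]]:
    """Seed matches in a 13-nt mRNA-sense flank with ``allele`` at the
    center.

    Returns (mirna id, window offset) pairs whose window is the exact
    reverse complement of the seed and covers the center position.  Flanks
    containing unknown bases are rejected.
    """
    flank = _rna(flank13)
    if len(flank) != 2 * CENTER + 1:
        raise ValueError(f"flank must be {2 * CENTER + 1} nt, got {len(flank)}")
    flank = flank[:CENTER] + _rna(allele) + flank[CENTER + 1 :]
    if any(b not in "AUCG" for b in flank):
        raise MirnaFormatError(f"flank contains non-AUCG base: {flank13}")
    hits: set[tuple[str, int]] = set()
    for mirna_id, seed in seeds.items():
        target = _revcomp_rna(seed)
        w = len(target)
        for offset in range(0, len(flank) - w + 1):
            if not offset <= CENTER < offset + w:
                continue
            if flank[offset : offset + w] == target:
                hits.add((mirna_id, offset))
    return hits


def classify_alteration(
    site_id: str,
    flank13: str,
    seeds: dict[str, str],
) -> list[MirnaHit]:
    """Compare seed matches between the A and G alleles of one 3'-UTR site.

    destroyed = matches of the A allele lost under G; created = matches
    gained under G; matches present under both alleles are reported as
    unchanged.
    """
    a_hits = scan_site(flank13, "A", seeds)
    g_hits = scan_site(flank13, "G", seeds)
    out: list[MirnaHit] = []
    for mirna_id, offset in sorted(a_hits - g_hits):
        out.append(MirnaHit(site_id, mirna_id, "destroyed", offset, "A"))
    for mirna_id, offset in sorted(g_hits - a_hits):
        out.append(MirnaHit(site_id, mirna_id, "created", offset, "G"))
    for mirna_id, offset in sorted(a_hits & g_hits):
        out.append(MirnaHit(site_id, mirna_id, "unchanged", offset, "A"))
    return out


def site_flank(bundle, chrom: str, pos: int, strand: str) -> str | None:
    """13-nt mRNA-sense genomic flank around a site; None at contig edges.

    Flanks are read from the genome (junction-spanning flanks in spliced
    transcripts are not reconstructed; callers may flag sites within 6 nt
    of an exon boundary)."""
    length = len(bundle.seqs[chrom])
    if pos - CENTER < 0 or pos + CENTER + 1 > length:
        return None
    return bundle.sequence(chrom, pos - CENTER, pos + CENTER + 1, strand)


def hits_to_tsv(hits: list[MirnaHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tmirna\tstatus\toffset\tallele\n")
        for h in hits:
            fh.write(f"{h.site_id}\t{h.mirna_id}\t{h.status}\t{h.offset}\t{h.allele}\n")
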