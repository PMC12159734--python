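"""Open-reading-frame extraction from unannotated genome scaffolds.

When a species arrives as bare contigs with no annotation, candidate gene
sequences are taken to be ORFs: an in-frame ATG through the next in-frame
stop codon, scanning all six reading frames.  Per stop codon (and frame)
the single longest ORF is reported — the one starting at the most 5'
in-frame ATG after the previous in-frame stop — which is the conventional
gene-proxy definition and avoids reporting every nested start.

ORFs truncated by a contig end (no stop codon reached) are discarded:
dangling ORFs are common on scaffolds and would violate the complete
start..stop contract.  Codons containing ``N`` never match ATG or a stop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .formats_io import GeneSeq, SeqRecord, _reverse_complement, make_gene_id

logger = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

DEFAULT_MIN_ORF_LEN = 300  # nt; ~100 aa, suppresses spurious short ORFs


def reverse_complement(residues: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet (N maps to N)."""
    return _reverse_complement(residues)


@dataclass(frozen=True)
class Orf:
    """A complete ORF with forward-strand coordinates.

    ``start``/``end`` are 0-based half-open on the forward strand no matter
    the strand; ``residues`` is read 5'->3' on the ORF's own strand, so it
    always begins ``ATG`` and ends with a stop codon.
    """

    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    frame: int  # 0, 1, 2 (offset on the scanned strand)
    residues: str


def _scan_strand(seq: str, min_orf_len: int):
    """Yield (strand_start, strand_end, frame, residues) on one strand.

    Coordinates are on the scanned strand; the caller reflects minus-strand
    hits back to forward coordinates.
    """
    n = len(seq)
    for frame in range(3):
        start_codon = -1  # most 5' ATG since the previous in-frame stop
        for i in range(frame, n - 2, 3):
            codon = seq[i : i + 3]
            if codon == "ATG" and start_codon < 0:
                start_codon = i
            elif codon in STOP_CODONS:
                if start_codon >= 0:
                    end = i + 3
                    if end - start_codon >= min_orf_len:
                        yield start_codon, end, frame, seq[start_codon:end]
                start_codon = -1


def find_orfs(record: SeqRecord, min_orf_len: int = DEFAULT_MIN_ORF_LEN) -> list[Orf]:
    """Scan all six frames of a contig for complete ORFs.

    ``min_orf_len`` is in nucleotides, must be >= 6 and divisible by 3
    (start plus stop codon at minimum).  Output is sorted by
    (start, end, strand) on forward coordinates.
    """
    if min_orf_len < 6 or min_orf_len % 3:
        raise ValueError("min_orf_len must be >= 6 and divisible by 3")
    seq = record.residues
    n = len(seq)
    orfs: list[Orf] = []
    for s, e, frame, res in _scan_strand(seq, min_orf_len):
        orfs.append(Orf(record.id, s, e, "+", frame, res))
    rc = reverse_complement(seq)
    for s, e, frame, res in _scan_strand(rc, min_orf_len):
        # reflect strand coordinates back to the forward strand
        orfs.append(Orf(record.id, n - e, n - s, "-", frame, res))
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def orfs_to_genes(
    species_id: str,
    contigs: list[SeqRecord],
    min_orf_len: int = DEFAULT_MIN_ORF_LEN,
) -> list[GeneSeq]:
    """Run the ORF scan over every contig of a species and label the
    results as candidate genes with origin ``orf``."""
    genes: list[GeneSeq] = []
    k = 0
    for rec in contigs:
        for orf in find_orfs(rec, min_orf_len):
            genes.append(
                GeneSeq(
                    species_id=species_id,
                    gene_id=make_gene_id(species_id, f"orf{k:05d}"),
                    residues=orf.residues,
                    origin="orf",
                    source_contig=orf.contig_id,
                    span=(orf.start, orf.end),
                    strand=orf.strand,
                )
            )
            k += 1
    logger.info("%s: %d ORFs >= %d nt", species_id, len(genes), min_orf_len)
    return genes


def write_orf_bed(orfs: list[Orf], path) -> None:
    """BED-like TSV dump (contig, start, end, strand) for inspection."""
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f"{o.contig_id}\t{o.start}\t{o.end}\t{o.strand}\n")
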