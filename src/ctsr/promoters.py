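"""Strand-aware promoter extraction from a genome FASTA.

The promoter of a gene is the L bases immediately upstream of its TSS,
oriented along the gene's strand: for '+' genes the 1-based closed interval
[max(1, tss−L), tss−1] read forward, for '−' genes [tss+1, tss+L] reverse-
complemented. Sequences are clipped at chromosome boundaries and N bases
are preserved.
"""
from __future__ import annotations

import logging
from pathlib import Path

from pyfaidx import Fasta

from .types import GeneAnnotation, PromoterRecord, PromoterSet

log = logging.getLogger("ctsr")

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def extract_promoters(
    annotation: GeneAnnotation,
    genome_fasta,
    length: int = 1000,
    genes: list[str] | None = None,
) -> PromoterSet:
    """Extract upstream promoter sequences for ``genes`` (default: all annotated)."""
    if length < 1:
        raise ValueError("promoter length must be >= 1")
    fasta = Fasta(str(genome_fasta), sequence_always_upper=True)
    wanted = genes if genes is not None else list(annotation.records)
    promoters: dict[str, PromoterRecord] = {}
    n_missing_ann = n_missing_chrom = n_empty = 0
    for gene_id in wanted:
        if gene_id not in annotation:
            n_missing_ann += 1
            continue
        rec = annotation[gene_id]
        if rec.chromosome not in fasta:
            n_missing_chrom += 1
            continue
        chrom_len = len(fasta[rec.chromosome])
        if rec.strand == "+":
            start, end = max(1, rec.tss - length), rec.tss - 1
        else:
            start, end = rec.tss + 1, min(chrom_len, rec.tss + length)
        if end < start:
            n_empty += 1
            continue
        seq = fasta[rec.chromosome][start - 1:end].seq
        if rec.strand == "-":
            seq = reverse_complement(seq)
        promoters[gene_id] = PromoterRecord(
            gene_id, seq, rec.chromosome, start, end, rec.strand
        )
    if n_missing_ann:
        log.warning("%d gene(s) absent from the annotation; skipped", n_missing_ann)
    if n_missing_chrom:
        log.warning("%d gene(s) on chromosomes absent from the FASTA; skipped", n_missing_chrom)
    if n_empty:
        log.warning("%d gene(s) with empty upstream region; skipped", n_empty)
    return PromoterSet(promoters, length)


def write_promoters_bed(promoters: PromoterSet, path) -> Path:
    """Write promoter intervals as 6-column BED (0-based half-open)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id in sorted(promoters.promoters):
            rec = promoters[gene_id]
            fh.write(
                f"{rec.chromosome}\t{rec.start - 1}\t{rec.end}\t{gene_id}\t0\t{rec.strand}\n"
            )
    return path
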