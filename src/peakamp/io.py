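"""Readers and writers for the plain-text genomics formats the pipeline uses.

chrom.sizes (two-column TSV), BED (3-6 columns), bedGraph (4-column),
gene-annotation TSV (gene_id, chrom, tss, tes, strand, with header), and
FASTA (via Biopython). All readers tolerate comment lines (#) and UCSC
``track``/``browser`` lines.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import GeneAnnotation, Genome, GenomicInterval, IntervalSet

_SKIP_PREFIXES = ("#", "track", "browser")


def _data_lines(path: str | os.PathLike) -> Iterable[list[str]]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or any(line.startswith(p) for p in _SKIP_PREFIXES):
                continue
            yield line.split("\t")


def read_chrom_sizes(path: str | os.PathLike) -> Genome:
    chroms = [(f[0], int(f[1])) for f in _data_lines(path)]
    if not chroms:
        raise ValueError(f"{path}: no chromosomes found")
    return Genome(chroms)


def write_chrom_sizes(genome: Genome, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome:
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | os.PathLike, name: str = "") -> IntervalSet:
    out = []
    for f in _data_lines(path):
        iv_name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "."
        out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand=strand, name=iv_name))
    return IntervalSet(out, name=name or os.path.basename(str(path)))


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )


GENE_TSV_COLUMNS = ("gene_id", "chrom", "tss", "tes", "strand")


def read_gene_tsv(path: str | os.PathLike) -> list[GeneAnnotation]:
    """Gene annotation TSV with a documented header line (gene_id chrom tss tes strand)."""
    rows = list(_data_lines(path))
    if rows and rows[0][0] == "gene_id":
        rows = rows[1:]
    return [
        GeneAnnotation(f[0], f[1], int(f[2]), int(f[3]), f[4]) for f in rows
    ]


def write_gene_tsv(genes: Sequence[GeneAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(GENE_TSV_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.tes}\t{g.strand}\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
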