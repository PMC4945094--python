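"""Readers and writers for the plain-text formats the pipeline consumes.

TSV marker maps and genotype matrices, BED6 intervals, FASTA haplotype
templates and paired FASTQ files.  FASTA/FASTQ go through Biopython.
"""

from __future__ import annotations

from typing import Iterator

import pandas as pd
from Bio import SeqIO

from .mapping import MarkerMap
from .pollen import AmpliconTemplate

__all__ = [
    "read_marker_map",
    "read_genotype_matrix",
    "read_bed",
    "write_bed",
    "read_template",
    "iter_fastq_pairs",
]


def read_marker_map(path, chrom: str | None = None,
                    flank_left_bp: int = 0, flank_right_bp: int = 0) -> MarkerMap:
    """Marker map TSV: columns marker, chrom, pos (1-based), col_allele, ler_allele."""
    df = pd.read_csv(path, sep="\t")
    return MarkerMap.from_frame(df, chrom=chrom, flank_left_bp=flank_left_bp,
                                flank_right_bp=flank_right_bp)


def write_marker_map(marker_map: MarkerMap, path) -> None:
    pd.DataFrame({
        "marker": marker_map.ids,
        "chrom": marker_map.chrom,
        "pos": marker_map.positions,
        "col_allele": marker_map.col_alleles or "N",
        "ler_allele": marker_map.ler_alleles or "N",
    }).to_csv(path, sep="\t", index=False)


def read_genotype_matrix(path) -> pd.DataFrame:
    """Genotype TSV: first column individual id, remaining columns markers (C/H/N)."""
    return pd.read_csv(path, sep="\t", index_col=0, dtype=str)


def read_bed(path) -> pd.DataFrame:
    """BED (>= 3 columns) into (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[:df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand")
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def read_template(col_fasta, ler_fasta, chrom: str = "amp",
                  offset_bp: int = 1) -> AmpliconTemplate:
    """Amplicon template from one-record Col and Ler FASTA files."""
    col = str(next(SeqIO.parse(str(col_fasta), "fasta")).seq)
    ler = str(next(SeqIO.parse(str(ler_fasta), "fasta")).seq)
    return AmpliconTemplate.from_sequences(col, ler, chrom=chrom, offset_bp=offset_bp)


def iter_fastq_pairs(fastq1, fastq2) -> Iterator[tuple[str, str, str]]:
    """Yield (pair_id, seq1, seq2) from two synchronized FASTQ files."""
    it1 = SeqIO.parse(str(fastq1), "fastq")
    it2 = SeqIO.parse(str(fastq2), "fastq")
    for r1, r2 in zip(it1, it2):
        pid = r1.id.rsplit("/", 1)[0]
        yield pid, str(r1.seq), str(r2.seq)
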