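"""File format helpers.

All tabular formats are plain TSV read/written through pandas. Sequences are
FASTA via Biopython. Genomic intervals are 0-based half-open internally;
GFF3 and cytosine reports use their native 1-based conventions and are
converted at the boundary.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FLOAT_FORMAT = "%.6g"

DEPTH_COLUMNS = ["chrom", "start", "end", "depth"]
TE_COLUMNS = ["chrom", "start", "end", "family", "te_class", "perc_div"]
CYTOSINE_COLUMNS = [
    "chrom",
    "pos",
    "strand",
    "context",
    "count_methylated",
    "count_unmethylated",
]
HOMOEOLOG_COLUMNS = ["pair_id", "gene_a", "gene_b", "diploid_ortholog", "chrom_a", "chrom_b"]
GENE_COLUMNS = ["chrom", "start", "end", "strand", "gene_id"]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | os.PathLike, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (genes only)

def read_gff3_genes(path: str | os.PathLike) -> pd.DataFrame:
    """Read gene features from a GFF3 file into a 0-based half-open table.

    Returns a DataFrame with columns ``chrom, start, end, strand, gene_id``.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            if fields[2] != "gene":
                continue
            attrs = dict(
                item.split("=", 1) for item in fields[8].split(";") if "=" in item
            )
            gene_id = attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"gene feature without ID attribute: {line!r}")
            rows.append(
                {
                    "chrom": fields[0],
                    "start": int(fields[3]) - 1,
                    "end": int(fields[4]),
                    "strand": fields[6],
                    "gene_id": gene_id,
                }
            )
    return pd.DataFrame(rows, columns=GENE_COLUMNS)


def write_gff3_genes(path: str | os.PathLike, genes: pd.DataFrame) -> None:
    """Write a gene table (0-based half-open) as GFF3 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(
                "\t".join(
                    [
                        row.chrom,
                        "allopoly",
                        "gene",
                        str(int(row.start) + 1),
                        str(int(row.end)),
                        ".",
                        row.strand,
                        ".",
                        f"ID={row.gene_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def write_tsv(path: str | os.PathLike, frame: pd.DataFrame, index: bool = False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def read_depth_tsv(path: str | os.PathLike) -> pd.DataFrame:
    frame = read_tsv(path)
    missing = set(DEPTH_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"depth table missing columns: {sorted(missing)}")
    return frame[DEPTH_COLUMNS]


def read_te_tsv(path: str | os.PathLike) -> pd.DataFrame:
    frame = read_tsv(path)
    missing = set(TE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"TE table missing columns: {sorted(missing)}")
    return frame


def read_cytosine_tsv(path: str | os.PathLike) -> pd.DataFrame:
    frame = read_tsv(path)
    missing = set(CYTOSINE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cytosine report missing columns: {sorted(missing)}")
    return frame[CYTOSINE_COLUMNS]


def read_fpkm_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read an FPKM matrix: first column gene id, remaining columns tissues."""
    frame = read_tsv(path, index_col=0)
    frame.index.name = "gene_id"
    return frame


def read_homoeolog_tsv(path: str | os.PathLike) -> pd.DataFrame:
    frame = read_tsv(path)
    missing = set(HOMOEOLOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"homoeolog table missing columns: {sorted(missing)}")
    return frame
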