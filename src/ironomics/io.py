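"""Readers and writers for the genomic text formats the pipeline consumes.

Coordinate conventions
----------------------
All in-memory coordinates are 0-based half-open.  Conversion happens only at
the I/O boundary:

* GTF            — 1-based inclusive on disk (``pyranges`` converts on read).
* bedGraph       — 0-based half-open on disk (native).
* narrowPeak     — 0-based half-open on disk (native, BED6+4).
* cytosine report— Bismark style, 1-based position on disk.
* junction TSV   — our own format; donor/acceptor are the intron's 0-based
  half-open [start, end) boundaries.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "read_gtf",
    "write_gtf",
    "read_fasta",
    "write_fasta",
    "read_bedgraph",
    "write_bedgraph",
    "depth_array",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_junctions",
    "write_junctions",
    "read_expression",
    "write_expression",
]

JUNCTION_COLUMNS = ["chrom", "donor", "acceptor", "strand", "count", "sample"]
EXPRESSION_COLUMNS = ["gene", "sample", "fpkm"]
CYTOSINE_COLUMNS = [
    "chrom", "pos", "strand", "count_methylated", "count_unmethylated",
    "context", "tricontext",
]
NARROWPEAK_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "signal", "pvalue", "qvalue", "summit",
]


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def read_gtf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GTF into a DataFrame with 0-based half-open Start/End."""
    import pyranges as pr

    df = pr.read_gtf(str(path)).df
    df["Chromosome"] = df["Chromosome"].astype(str)
    df["Strand"] = df["Strand"].astype(str)
    df["Feature"] = df["Feature"].astype(str)
    return df


def write_gtf(df: pd.DataFrame, path: str | os.PathLike, source: str = "ironomics") -> None:
    """Write gene/transcript/exon rows (internal 0-based) as 1-based GTF.

    Expects columns Chromosome, Feature, Start, End, Strand, gene_id and,
    where applicable, transcript_id and exon_number.
    """
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            attrs = [f'gene_id "{row.gene_id}";']
            tid = getattr(row, "transcript_id", None)
            if isinstance(tid, str) and tid:
                attrs.append(f'transcript_id "{tid}";')
            num = getattr(row, "exon_number", None)
            if num is not None and not (isinstance(num, float) and np.isnan(num)):
                attrs.append(f'exon_number "{int(num)}";')
            fh.write(
                "\t".join(
                    [
                        str(row.Chromosome),
                        source,
                        str(row.Feature),
                        str(int(row.Start) + 1),
                        str(int(row.End)),
                        ".",
                        str(row.Strand),
                        ".",
                        " ".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike):
    """Open a FASTA for random access (pyfaidx.Fasta)."""
    from pyfaidx import Fasta

    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        comment="t",  # skips optional "track" header lines
    )
    return df


def write_bedgraph(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=["chrom", "start", "end", "value"])


def bedgraph_from_array(values: np.ndarray, chrom: str) -> pd.DataFrame:
    """Run-length encode a per-base array into bedGraph rows (zeros dropped)."""
    values = np.asarray(values)
    if len(values) == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "value"])
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    vals = values[starts]
    keep = vals != 0
    return pd.DataFrame(
        {"chrom": chrom, "start": starts[keep], "end": ends[keep], "value": vals[keep]}
    )


def depth_array(bedgraph: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    """Expand bedGraph rows for one chromosome into a dense per-base array."""
    out = np.zeros(length, dtype=float)
    sub = bedgraph[bedgraph["chrom"] == chrom]
    for start, end, value in zip(sub["start"], sub["end"], sub["value"]):
        out[int(start) : int(end)] = value
    return out


# ---------------------------------------------------------------------------
# Bismark-style cytosine report
# ---------------------------------------------------------------------------

def write_cytosine_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write calls (0-based internal ``pos``) as a 1-based cytosine report."""
    out = df.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out.to_csv(path, sep="\t", header=False, index=False, columns=CYTOSINE_COLUMNS)


def read_cytosine_report(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=CYTOSINE_COLUMNS,
                     dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df


# ---------------------------------------------------------------------------
# narrowPeak (BED6+4)
# ---------------------------------------------------------------------------

def write_narrowpeak(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", header=False, index=False, columns=NARROWPEAK_COLUMNS)


def read_narrowpeak(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None, names=NARROWPEAK_COLUMNS,
                       dtype={"chrom": str})


# ---------------------------------------------------------------------------
# Plain TSV tables
# ---------------------------------------------------------------------------

def write_junctions(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=JUNCTION_COLUMNS)


def read_junctions(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})


def write_expression(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, columns=EXPRESSION_COLUMNS)


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene": str, "sample": str})
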