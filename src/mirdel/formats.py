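"""Reading and writing of the flat-file formats used by the pipeline.

FASTA and FASTQ go through Biopython.  GFF3 (1-based inclusive coordinates,
``key=value`` attribute column) is round-tripped through a small pandas-based
reader/writer; the annotation files here are flat interval lists, never
hierarchical models.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

GFF3_COLUMNS = [
    "seqid",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(name, sequence)`` pairs to a FASTA file."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ordered ``name -> sequence`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str, str]]) -> int:
    """Write ``(id, sequence, quality)`` triples as 4-line FASTQ records."""
    n = 0
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, str]]:
    """Iterate ``(id, sequence, quality)`` from a 4-line FASTQ file."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper(), qual


def format_attributes(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for field in str(text).strip().split(";"):
        if not field:
            continue
        key, _, value = field.partition("=")
        out[key] = value
    return out


def write_gff3(path: str | os.PathLike, rows: Iterable[dict]) -> None:
    """Write feature dicts (GFF3 column names, ``attributes`` as dict) to GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in rows:
            attrs = row.get("attributes", {})
            if isinstance(attrs, dict):
                attrs = format_attributes(attrs)
            fh.write(
                "\t".join(
                    [
                        str(row["seqid"]),
                        str(row.get("source", "mirdel")),
                        str(row["type"]),
                        str(int(row["start"])),
                        str(int(row["end"])),
                        str(row.get("score", ".")),
                        str(row.get("strand", "+")),
                        str(row.get("phase", ".")),
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3(path: str | os.PathLike) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame; attribute values become columns.

    Coordinates stay 1-based inclusive, as in the file.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=GFF3_COLUMNS,
        dtype={"seqid": str},
    )
    attr_df = pd.DataFrame([parse_attributes(a) for a in df["attributes"]])
    df = pd.concat([df.drop(columns=["attributes"]), attr_df], axis=1)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def parse_interval(text: str) -> tuple[str, int, int]:
    """Parse ``contig:start-end`` (1-based inclusive) into a tuple."""
    contig, _, span = text.partition(":")
    lo, sep, hi = span.replace("_", "-").partition("-")
    if not contig or not sep:
        raise ValueError(f"expected 'contig:start-end', got {text!r}")
    start, end = int(lo.replace(",", "")), int(hi.replace(",", ""))
    if start > end:
        raise ValueError(f"interval start {start} > end {end} in {text!r}")
    return contig, start, end
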