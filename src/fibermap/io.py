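"""Format I/O at the pipeline boundaries.

Coordinate conventions: VCF and GFF3 are 1-based inclusive, BED is
0-based half-open, and all internal arithmetic is 0-based half-open;
conversions happen only here. VCF goes through pysam
(:mod:`fibermap.variants`), FASTA through Biopython, tables through
pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ltr import LTRAnnotation

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_table",
    "read_table",
    "write_bed",
    "write_gff3",
]


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_table(df: pd.DataFrame, path, sep: str = "\t", index: bool = False) -> None:
    df.to_csv(path, sep=sep, index=index)


def read_table(path, sep: str = "\t", **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, **kw)


def write_bed(bins: pd.DataFrame, path, name_col: str | None = "count") -> None:
    """Write windows (already 0-based half-open) as BED4."""
    out = bins[["chrom", "start", "end"]].copy()
    if name_col is not None:
        out["name"] = bins[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)


def write_gff3(
    annotations: Mapping[str, LTRAnnotation], path, source: str = "fibermap"
) -> None:
    """Write LTR annotations as GFF3 (1-based inclusive coordinates)."""
    lines = ["##gff-version 3"]
    for seqid, ann in annotations.items():
        if ann is None:
            continue
        attrs = f"ID={seqid}.element;ltr_identity={ann.identity:.4f}"
        if ann.tsd:
            attrs += f";tsd={ann.tsd}"
        element = (
            seqid, source, "mobile_genetic_element",
            ann.start + 1, ann.end, ".", "+", ".", attrs,
        )
        ltr5 = (
            seqid, source, "long_terminal_repeat",
            ann.start + 1, ann.start + ann.ltr5_length, ".", "+", ".",
            f"ID={seqid}.ltr5;Parent={seqid}.element",
        )
        ltr3 = (
            seqid, source, "long_terminal_repeat",
            ann.end - ann.ltr3_length + 1, ann.end, ".", "+", ".",
            f"ID={seqid}.ltr3;Parent={seqid}.element",
        )
        for feat in (element, ltr5, ltr3):
            lines.append("\t".join(str(x) for x in feat))
    Path(path).write_text("\n".join(lines) + "\n")
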