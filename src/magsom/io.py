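"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython; tables are pandas TSV. Writers are
deliberately plain (fixed field order, ``\\n`` endings, repr-stable floats)
so that identical inputs produce byte-identical files.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA -> {record id: uppercase sequence}."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    """FASTQ -> [(read id, sequence), ...] in file order."""
    with _open_text(path) as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path, quality_char: str = "I") -> None:
    """Write (id, sequence) pairs as Phred+33 FASTQ with constant quality."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
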