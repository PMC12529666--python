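"""File-format plumbing: FASTA/FASTQ via Biopython, tables via pandas.

Sequences are normalized to the RNA alphabet on input (T -> U), matching
the rest of the package.  FASTQ quality strings are constant on write (the
pipeline uses no quality information).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from agodyn.isomirs import CanonicalMiRNA
from agodyn.seeds import GuideRNA

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_guides",
    "read_canonical_mirnas",
    "read_fastq_seqs",
    "write_fastq",
    "read_table",
    "write_table",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Name -> RNA sequence (T normalized to U)."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper().replace("T", "U") for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


def read_guides(path) -> list[GuideRNA]:
    return [GuideRNA(name, seq) for name, seq in read_fasta(path).items()]


def read_canonical_mirnas(path) -> list[CanonicalMiRNA]:
    """Canonical mature miRNAs from FASTA with names ``<precursor>-<arm>``."""
    out = []
    for name, seq in read_fasta(path).items():
        prec, _, arm = name.rpartition("-")
        if arm in ("5p", "3p"):
            out.append(CanonicalMiRNA(name, seq, precursor=prec, arm=arm))
        else:
            out.append(CanonicalMiRNA(name, seq))
    return out


def read_fastq_seqs(path) -> Iterator[str]:
    """Yield read sequences (RNA alphabet) from a FASTQ file (gzip-aware)."""
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq).upper().replace("T", "U")


def write_fastq(path, reads: Iterable[str], prefix: str = "read") -> None:
    with _open(path, "wt") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i + 1}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
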