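"""File plumbing: FASTA/FASTQ via Biopython, TSV via pandas.

FASTQ quality strings are constant Phred-30 (``'?'``); nothing downstream
consumes qualities.  All writers are deterministic given their inputs.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import DataError
from .simulate import SimulatedRead

QUALITY_CHAR = "?"  # Phred 30


def _records(path: str | os.PathLike, fmt: str):
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    return SeqIO.parse(str(path), fmt)


def read_sequences(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read (id, sequence) pairs from FASTA or FASTQ, sniffed by extension."""
    suffix = Path(path).suffix.lower()
    fmt = "fastq" if suffix in {".fastq", ".fq"} else "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in _records(path, fmt)]


def write_fasta(path: str | os.PathLike,
                entries: Iterable[tuple[str, str]]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in entries]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def write_fastq(path: str | os.PathLike,
                reads: Sequence[SimulatedRead]) -> None:
    """4-line FASTQ records with constant quality."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                     f"{QUALITY_CHAR * len(read.sequence)}\n")


def write_truth_tsv(path: str | os.PathLike,
                    reads: Sequence[SimulatedRead]) -> None:
    df = pd.DataFrame({
        "read_id": [r.read_id for r in reads],
        "strand": [r.strand for r in reads],
        "true_class": [r.truth.span_class for r in reads],
        "true_core_count": [r.truth.core_count if r.truth.core_count is not None
                            else "" for r in reads],
        "allele_id": [r.truth.allele_id for r in reads],
    })
    write_tsv(path, df)


def write_tsv(path: str | os.PathLike, df: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    if not Path(path).exists():
        raise DataError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t")


def write_bed(path: str | os.PathLike,
              rows: Iterable[tuple[str, int, int]]) -> None:
    """3-column BED, 0-based half-open."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, start, end in rows:
            fh.write(f"{name}\t{start}\t{end}\n")
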