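"""FASTA/FASTQ/TSV input and output.

Sequences are parsed with Bio.SeqIO, upper-cased with U normalized to T, and
validated over {A,C,G,T,N}; duplicate ids are an error. FASTA output is
60-column wrapped. TSV round-trips losslessly through pandas.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import validate_nucleotides
from .errors import InputError
from .simgen import Read


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".fq", ".fastq"):
        return "fastq"
    if suffix in (".fa", ".fasta", ".fna"):
        return "fasta"
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return "fastq"
    if first == ">":
        return "fasta"
    raise InputError(f"{path}: cannot determine sequence format")


def read_sequences(path: str | os.PathLike) -> list[Read]:
    """Parse FASTA or FASTQ into Read records (upper-case, U -> T)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    fmt = _detect_format(path)
    reads: list[Read] = []
    seen: set[str] = set()
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seq = str(rec.seq).upper().replace("U", "T")
            validate_nucleotides(seq, context=f"{path}:{rec.id}")
            if rec.id in seen:
                raise InputError(f"{path}: duplicate sequence id {rec.id!r}")
            seen.add(rec.id)
            reads.append(Read(id=rec.id, seq=seq))
    except ValueError as exc:  # malformed FASTQ etc.
        raise InputError(f"{path}: {exc}") from exc
    if not reads:
        raise InputError(f"{path}: no sequence records found")
    return reads


def write_sequences(
    reads: list[Read], path: str | os.PathLike, *, fmt: str = "fasta"
) -> None:
    """Write reads as 60-column FASTA (or FASTQ with uniform quality 30)."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.seq), id=r.id, description="")
        if fmt == "fastq":
            rec.letter_annotations["phred_quality"] = [30] * len(r.seq)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"{path}: no such file")
    try:
        return pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise InputError(f"{path}: {exc}") from exc


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
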