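"""Readers and writers for the formats the toolkit touches.

Sequence input is FASTA or FASTQ, optionally gzip-compressed (detected by
magic bytes, not extension). Abundance profiles are two-column TSV tables
(``species``, ``abundance``). Spectra are written as TSV with columns
``q``, ``D``, ``r_squared``.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadSet",
    "AbundanceProfile",
    "read_sequences",
    "write_fasta",
    "read_abundance_table",
    "write_abundance_table",
]

_GZIP_MAGIC = b"\x1f\x8b"
_SUM_TOL = 1e-6


@dataclass
class ReadSet:
    """Ordered collection of nucleotide reads with identifiers.

    Sequences are stored uppercased; identifiers are preserved verbatim.
    """

    reads: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, (_, seq) in enumerate(self.reads):
            if not seq:
                raise ValueError(f"read {i} has an empty sequence")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.reads)

    @property
    def identifiers(self) -> list[str]:
        return [rid for rid, _ in self.reads]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.reads]

    @classmethod
    def from_sequences(cls, sequences: Sequence[str], prefix: str = "read") -> "ReadSet":
        """Wrap bare sequences, generating ``prefix_<i>`` identifiers."""
        return cls([(f"{prefix}_{i}", s.upper()) for i, s in enumerate(sequences)])


@dataclass
class AbundanceProfile:
    """Species labels with relative abundances summing to 1 (zeros allowed)."""

    labels: list[str]
    abundances: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if len(self.labels) != self.abundances.size:
            raise ValueError("labels and abundances differ in length")
        if np.any(self.abundances < 0):
            raise ValueError("abundances must be non-negative")
        total = float(self.abundances.sum())
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"abundances sum to {total}, not 1 within {_SUM_TOL}")
        # exact renormalization so downstream sums hit 1 to machine precision
        self.abundances = self.abundances / total

    def __len__(self) -> int:
        return len(self.labels)


def _open_maybe_gzip(path: Path) -> _io.TextIOWrapper:
    with open(path, "rb") as raw:
        magic = raw.read(2)
    if magic == _GZIP_MAGIC:
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _sniff_format(handle: _io.TextIOWrapper) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError("cannot determine sequence format: file starts with neither '>' nor '@'")


def read_sequences(path: str | Path, format_hint: str = "auto") -> ReadSet:
    """Parse a FASTA or FASTQ file (plain or gzipped) into a :class:`ReadSet`.

    Parameters
    ----------
    path:
        Input file. gzip compression is detected from the first two bytes.
    format_hint:
        ``"fasta"``, ``"fastq"``, or ``"auto"`` (resolve from extension,
        falling back to the first byte: ``>`` vs ``@``).

    FASTQ quality strings are discarded; only nucleotide symbols are used
    downstream. Sequences are uppercased. Records are returned in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format_hint not in ("fasta", "fastq", "auto"):
        raise ValueError(f"unknown format hint {format_hint!r}")

    handle = _open_maybe_gzip(path)
    try:
        fmt = format_hint
        if fmt == "auto":
            stem = path.name.removesuffix(".gz")
            if stem.endswith((".fasta", ".fa", ".fna")):
                fmt = "fasta"
            elif stem.endswith((".fastq", ".fq")):
                fmt = "fastq"
            else:
                fmt = _sniff_format(handle)
        reads: list[tuple[str, str]] = []
        try:
            for rec in SeqIO.parse(handle, fmt):
                seq = str(rec.seq).upper()
                if not seq:
                    raise ValueError(f"record {len(reads)} ({rec.id!r}) has an empty sequence")
                reads.append((rec.description or rec.id, seq))
        except ValueError as exc:
            raise ValueError(f"malformed {fmt} record near index {len(reads)}: {exc}") from exc
    finally:
        handle.close()
    return ReadSet(reads)


def write_fasta(readset: ReadSet, path: str | Path, compress: bool = False) -> Path:
    """Write a read set as (optionally gzipped) FASTA, one line per sequence."""
    path = Path(path)
    opener = gzip.open if compress else open
    with opener(path, "wt") as out:
        for rid, seq in readset:
            out.write(f">{rid}\n{seq}\n")
    return path


def read_abundance_table(path: str | Path) -> AbundanceProfile:
    """Read a two-column TSV (``species``, ``abundance``) into a profile.

    Abundances must be non-negative and sum to 1 within 1e-6; they are then
    renormalized to sum to 1 exactly.
    """
    df = pd.read_csv(path, sep="\t")
    missing = {"species", "abundance"} - set(df.columns)
    if missing:
        raise ValueError(f"abundance table {path} lacks columns: {sorted(missing)}")
    values = df["abundance"].to_numpy(dtype=float)
    if np.any(values < 0):
        bad = int(np.argmax(values < 0))
        raise ValueError(f"negative abundance at row {bad} of {path}")
    return AbundanceProfile(df["species"].astype(str).tolist(), values)


def write_abundance_table(profile: AbundanceProfile, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"species": profile.labels, "abundance": profile.abundances}).to_csv(
        path, sep="\t", index=False
    )
    return path
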