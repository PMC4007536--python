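"""Sequence, alignment and tabular I/O shared by every pipeline stage.

Coordinate convention: all intervals are 0-based half-open internally;
anything written to a report is 1-based inclusive.  DNA is held uppercase
over the alphabet {A, C, G, T, N}; IUPAC ambiguity codes other than N are
mapped to N with a logged warning.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

log = logging.getLogger("telifecycle")

DNA_ALPHABET = frozenset("ACGTN")
GAP_ALPHABET = frozenset("ACGTN-")

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stderr logging in 'LEVEL timestamp message' format."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(asctime)s %(message)s"))
    log.handlers[:] = [handler]
    log.setLevel(level)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gaps and N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_dna(seq: str) -> str:
    """Uppercase and map non-{ACGTN} characters to N (warning logged once per call)."""
    s = seq.upper()
    if not set(s) <= DNA_ALPHABET:
        bad = sorted(set(s) - DNA_ALPHABET)
        log.warning("ambiguity codes %s mapped to N", "".join(bad))
        s = "".join(c if c in DNA_ALPHABET else "N" for c in s)
    return s


class FormatError(ValueError):
    """Raised for malformed sequence or alignment input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.seq) < 1:
            raise FormatError(f"sequence record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomeInterval:
    """0-based half-open interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def to_report(self) -> tuple[int, int]:
        """1-based inclusive (start, end) for text outputs."""
        return self.start + 1, self.end

    @classmethod
    def from_report(cls, contig: str, start1: int, end1: int, strand: str = "+") -> "GenomeInterval":
        return cls(contig, start1 - 1, end1, strand)

    def overlap(self, other: "GenomeInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class Alignment:
    """A gapped multiple alignment: equal-length rows over {A,C,G,T,N,-}."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise FormatError("empty alignment")
        L = len(self.rows[0])
        if L < 1:
            raise FormatError("alignment with zero columns")
        for i, r in zip(self.ids, self.rows):
            if len(r) != L:
                raise FormatError(
                    f"ragged alignment: row {i!r} has length {len(r)}, expected {L}"
                )
        if len(self.ids) != len(self.rows):
            raise FormatError("ids/rows length mismatch")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        return "".join(r[j] for r in self.rows)

    @classmethod
    def from_records(cls, records: Sequence[SequenceRecord]) -> "Alignment":
        return cls([r.id for r in records], [r.seq for r in records])


def _sniff_fastq(path: Path) -> bool:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                return line.startswith("@")
    return False


def read_fasta(path: str | Path, allow_fastq: bool = True) -> list[SequenceRecord]:
    """Read FASTA (or FASTQ, qualities discarded) into SequenceRecords.

    Sequences are uppercased; ambiguity codes other than N become N.
    Duplicate ids raise FormatError.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = "fasta"
    if allow_fastq and (path.suffix in (".fq", ".fastq") or _sniff_fastq(path)):
        fmt = "fastq"
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), fmt):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, clean_dna(str(rec.seq)), rec.description))
    if not records:
        raise FormatError(f"no sequence records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA; gaps preserved, ragged rows rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        ids.append(rec.id)
        s = str(rec.seq).upper()
        if not set(s) <= GAP_ALPHABET:
            s = "".join(c if c in GAP_ALPHABET else "N" for c in s)
        rows.append(s)
    if not rows:
        raise FormatError(f"no alignment rows in {path}")
    return Alignment(ids, rows)


def write_tsv(table: pd.DataFrame | list[dict], path: str | Path) -> None:
    """Write a table as UTF-8 TSV, header first, floats at 6 significant digits."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", encoding="utf-8")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Load a YAML config and apply flat key overrides (CLI wins over file)."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise FormatError(f"config {path} is not a mapping")
            cfg = loaded
    for key, val in (overrides or {}).items():
        if val is not None:
            cfg[key] = val
    return cfg
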