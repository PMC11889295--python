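"""Readers, writers and metadata containers for the formats the pipeline touches.

All genomic and construct coordinates in this package are 1-based inclusive;
any half-open representation used internally is converted at the boundary.
"""

from __future__ import annotations

import csv
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio import SeqIO

from ._sequence import validate_dna

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional per-base Phred qualities."""

    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = validate_dna(self.sequence, name=self.id or "record")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"{self.id}: quality length {len(self.quality)} != sequence "
                f"length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ConstructAnnotation:
    """Transformation-construct annotation: T-DNA interval and named features.

    Intervals are 1-based inclusive ``(start, end)`` tuples on the construct.
    """

    construct_id: str
    length: int
    tdna_interval: tuple[int, int]
    features: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        s, e = self.tdna_interval
        if not (1 <= s <= e <= self.length):
            raise ValueError(f"T-DNA interval {self.tdna_interval} outside [1, {self.length}]")
        for name, (fs, fe) in self.features.items():
            if not (1 <= fs <= fe <= self.length):
                raise ValueError(f"feature {name!r} interval ({fs}, {fe}) outside construct")

    @property
    def tdna_length(self) -> int:
        return self.tdna_interval[1] - self.tdna_interval[0] + 1


@dataclass
class SampleEntry:
    sample_id: str
    role: str  # negative_control | positive_control | query
    generation: str = ""
    read_paths: list[str] = field(default_factory=list)


@dataclass
class SampleSheet:
    entries: list[SampleEntry]

    def __post_init__(self) -> None:
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in sample sheet")
        roles = {"negative_control", "positive_control", "query"}
        for e in self.entries:
            if e.role not in roles:
                raise ValueError(f"{e.sample_id}: unknown role {e.role!r}")
        n_neg = sum(e.role == "negative_control" for e in self.entries)
        if n_neg != 1:
            raise ValueError(f"sample sheet needs exactly one negative_control, found {n_neg}")

    @property
    def negative_control(self) -> SampleEntry:
        return next(e for e in self.entries if e.role == "negative_control")

    @property
    def non_controls(self) -> list[SampleEntry]:
        return [e for e in self.entries if e.role != "negative_control"]


def _open_maybe_gzip(path: str | Path, mode: str = "rt") -> IO:
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # fixed mtime keeps outputs byte-identical across runs
            import io as _io

            return _io.TextIOWrapper(gzip.GzipFile(path, "wb", mtime=0))
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into memory; sequences are uppercased and validated.

    Empty files yield an empty list (with a logged warning); an empty sequence
    or header raises :class:`FormatError` naming the offending record.
    """
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            seq = str(rec.seq)
            if not rec.id:
                raise FormatError(f"{path}: record {len(records) + 1} has an empty header")
            if not seq:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            try:
                records.append(SequenceRecord(rec.id, seq))
            except ValueError as exc:
                raise FormatError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        logger.warning("FASTA file %s contained no records", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream a (possibly gzipped) FASTQ file lazily, one record at a time.

    Qualities are retained on the records but the k-mer screen ignores them.
    Truncated records and sequence/quality length mismatches raise
    :class:`FormatError` carrying the 1-based record index.
    """
    index = 0
    with _open_maybe_gzip(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                index += 1
                quals = rec.letter_annotations.get("phred_quality")
                yield SequenceRecord(rec.id, str(rec.seq), list(quals) if quals else None)
        except ValueError as exc:
            raise FormatError(f"{path}: malformed FASTQ at record {index + 1}: {exc}") from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            qual = rec.quality if rec.quality is not None else [40] * len(rec.sequence)
            qline = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qline}\n")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read a TSV sample sheet: sample_id, role, generation, read_paths.

    ``read_paths`` holds one or more paths separated by semicolons.
    """
    entries = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "role", "generation", "read_paths"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
        for row in reader:
            paths = [p for p in row["read_paths"].split(";") if p]
            entries.append(SampleEntry(row["sample_id"], row["role"], row["generation"], paths))
    return SampleSheet(entries)


def read_features_tsv(path: str | Path, *, construct: SequenceRecord) -> ConstructAnnotation:
    """Build a :class:`ConstructAnnotation` from a 4-column feature TSV.

    Columns: name, start, end, strand (1-based inclusive). A row named
    ``T-DNA`` (case-insensitive) defines the T-DNA interval; it is also kept
    as a regular feature.
    """
    features: dict[str, tuple[int, int]] = {}
    tdna = None
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "start", "end"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise FormatError(f"{path}: feature table needs columns {sorted(required)}")
        for row in reader:
            iv = (int(row["start"]), int(row["end"]))
            features[row["name"]] = iv
            if row["name"].upper().replace("_", "-") == "T-DNA":
                tdna = iv
    if tdna is None:
        raise FormatError(f"{path}: no 'T-DNA' feature row defining the T-DNA interval")
    return ConstructAnnotation(construct.id, len(construct), tdna, features)


def write_features_tsv(annotation: ConstructAnnotation, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["name", "start", "end", "strand"])
        writer.writerow(["T-DNA", *annotation.tdna_interval, "+"])
        for name, (s, e) in annotation.features.items():
            if name.upper().replace("_", "-") == "T-DNA":
                continue
            writer.writerow([name, s, e, "+"])
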