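"""Readers and writers for the standard formats the pipeline touches:
FASTA/FASTQ reads, 12-column tabular hit files, and the annotation
table TSV.  No science lives here."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .records import AnnotationRecord, NAMESPACE_ORDER

PathLike = Union[str, Path]

#: column order of the annotation TSV
ANNOTATION_COLUMNS = ("read_id", "cog", "category", "kegg", "pfam", "go", "seed")
MISSING = "-"
MULTI_SEP = ";"


class ParseError(ValueError):
    """Malformed input file; the message carries a location."""


@dataclass(frozen=True)
class ReadRecord:
    """One nucleotide read. Sequences are uppercased on ingestion;
    N is the only ambiguity code accepted."""

    read_id: str
    nt_sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if not self.nt_sequence:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.nt_sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.nt_sequence)}"
            )


@dataclass(frozen=True)
class ExternalHitRow:
    """One row of a 12-column tabular hit file from an external search
    engine (the common outfmt-6 dialect; coordinates 1-based inclusive)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}/{self.subject_id}: negative evalue")


def _detect_format(path: Path, format: str) -> str:
    if format in ("fasta", "fastq"):
        return format
    if format != "auto":
        raise ValueError(f"unknown format {format!r}")
    suffix = path.suffix.lower()
    if suffix in (".fa", ".fasta", ".fna", ".ffn"):
        return "fasta"
    if suffix in (".fq", ".fastq"):
        return "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ParseError(f"{path}: cannot detect format from extension or first character")


def read_sequences(path: PathLike, format: str = "auto") -> list[ReadRecord]:
    """Read FASTA or FASTQ into ReadRecords, preserving file order.

    Sequences are uppercased; duplicate ids and length-mismatched
    FASTQ records are rejected with a location in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    records: list[ReadRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        if fmt == "fasta":
            for n, (title, seq) in enumerate(SimpleFastaParser(fh)):
                read_id = title.split()[0] if title.split() else ""
                if not read_id:
                    raise ParseError(f"{path}: record {n + 1} has an empty id")
                _check_duplicate(read_id, seen, path)
                records.append(ReadRecord(read_id, seq.upper()))
        else:
            n = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    read_id = title.split()[0]
                    _check_duplicate(read_id, seen, path)
                    if len(qual) != len(seq):
                        raise ParseError(
                            f"{path}: near line {4 * n + 1}: sequence/quality "
                            f"length mismatch for {read_id}"
                        )
                    records.append(ReadRecord(read_id, seq.upper(), qual))
                    n += 1
            except ValueError as exc:
                if isinstance(exc, ParseError):
                    raise
                raise ParseError(f"{path}: near line {4 * n + 1}: {exc}") from exc
    return records


def _check_duplicate(read_id: str, seen: set[str], path: Path) -> None:
    if read_id in seen:
        raise ParseError(f"{path}: duplicate read_id {read_id!r}")
    seen.add(read_id)


def parse_external_hits(path: PathLike) -> list[ExternalHitRow]:
    """Parse a 12-column tab-separated hit file; '#' comments skipped."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[ExternalHitRow] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                rows.append(
                    ExternalHitRow(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def _format_cell(terms: frozenset[str]) -> str:
    return MULTI_SEP.join(sorted(terms)) if terms else MISSING


def _parse_cell(cell: str) -> frozenset[str]:
    return frozenset() if cell == MISSING else frozenset(cell.split(MULTI_SEP))


def write_annotation_table(records: Iterable[AnnotationRecord], path: PathLike) -> None:
    """Serialize annotation records as TSV.

    Multi-valued cells are ';'-joined (sorted), empty cells are '-';
    the layout round-trips losslessly through read_annotation_table.
    """
    with open(path, "w") as fh:
        fh.write(f"# multi-value separator {MULTI_SEP!r}; missing value {MISSING!r}\n")
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for rec in records:
            cells = [rec.read_id]
            for ns in NAMESPACE_ORDER:
                cells.append(_format_cell(rec.labels.get(ns, frozenset())))
            fh.write("\t".join(cells) + "\n")


def read_annotation_table(path: PathLike) -> list[AnnotationRecord]:
    """Companion reader for write_annotation_table."""
    path = Path(path)
    records: list[AnnotationRecord] = []
    with open(path) as fh:
        header_seen = False
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if tuple(line.split("\t")) != ANNOTATION_COLUMNS:
                    raise ParseError(f"{path}: line {lineno}: unexpected header")
                header_seen = True
                continue
            fields = line.split("\t")
            if len(fields) != len(ANNOTATION_COLUMNS):
                raise ParseError(
                    f"{path}: line {lineno}: expected "
                    f"{len(ANNOTATION_COLUMNS)} columns, got {len(fields)}"
                )
            labels = {
                ns: _parse_cell(cell) for ns, cell in zip(NAMESPACE_ORDER, fields[1:])
            }
            records.append(AnnotationRecord(read_id=fields[0], labels=labels))
    return records
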