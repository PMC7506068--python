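"""Sequence and alignment I/O plus long-read quality filtering.

Formats handled: FASTA (80-column wrap on write), 4-line FASTQ with
Phred+33 qualities, and a SAM subset (QNAME, FLAG, RNAME, POS, MAPQ,
CIGAR restricted to M/I/D/S, SEQ). Internal coordinates are 0-based
half-open; the SAM boundary converts from/to 1-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SequenceRecord",
    "AlignmentRecord",
    "FormatError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_alignments",
    "write_alignments",
    "cigar_reference_span",
    "qc_filter_long_reads",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed FASTA/FASTQ/SAM input; message names the line."""


class ConfigurationError(ValueError):
    """Raised when an operation is invoked with inconsistent settings/data."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with optional quality.

    ``quality`` is either a single read-level score in [0, 100] (long
    reads), a per-base list of Phred scores (short reads), or None.
    """

    id: str
    sequence: str
    quality: float | list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.sequence) == 0:
            raise ValueError(f"sequence {self.id!r} is empty")
        if isinstance(self.quality, list) and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AlignmentRecord:
    """A read placement on a contig; start/end are 0-based half-open."""

    read_id: str
    contig_id: str
    start: int
    end: int
    strand: str  # "+" or "-"
    score: int = 0
    is_primary: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"alignment {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"alignment {self.read_id!r}: bad strand {self.strand!r}")

    @property
    def reference_span(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA; one record per header, sequences uppercased."""
    records: list[SequenceRecord] = []
    current_id: str | None = None
    chunks: list[str] = []
    header_line = 0

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}: empty sequence for {current_id!r} (line {header_line})")
        records.append(SequenceRecord(current_id, seq))

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise FormatError(f"{path}: malformed header at line {lineno}")
                header_line = lineno
                chunks = []
            else:
                if current_id is None:
                    raise FormatError(f"{path}: sequence before header at line {lineno}")
                chunks.append(line.strip().upper())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read 4-line FASTQ with Phred+33 per-base qualities."""
    records: list[SequenceRecord] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ record near line {len(lines)}")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"{path}: expected '@' at line {i + 1}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}: expected '+' at line {i + 3}")
        if len(seq) != len(qual):
            raise FormatError(f"{path}: sequence/quality length mismatch at line {i + 2}")
        rid = head[1:].split()[0]
        records.append(SequenceRecord(rid, seq.upper(), [ord(c) - 33 for c in qual]))
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec.quality, list):
                qual = "".join(chr(q + 33) for q in rec.quality)
            else:
                # read-level score in [0, 100]: emit it as a flat per-base
                # line (clamped to the printable Phred+33 range) so the
                # score survives a round-trip as the per-base mean
                value = 30 if rec.quality is None else int(round(rec.quality))
                qual = chr(33 + max(0, min(93, value))) * len(rec.sequence)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# SAM subset

_CIGAR_RE = re.compile(r"(\d+)([A-Z=])")
_REF_CONSUMING = {"M", "D"}
_SUPPORTED_OPS = {"M", "I", "D", "S"}


def cigar_reference_span(cigar: str) -> int:
    """Reference-consumed bases for a CIGAR over M/I/D/S."""
    span = 0
    matched = 0
    for m in _CIGAR_RE.finditer(cigar):
        n, op = int(m.group(1)), m.group(2)
        if op not in _SUPPORTED_OPS:
            raise FormatError(f"unsupported CIGAR operator {op!r} in {cigar!r}")
        if op in _REF_CONSUMING:
            span += n
        matched += len(m.group(0))
    if matched != len(cigar):
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return span


def read_alignments(path: str | Path) -> tuple[list[AlignmentRecord], int]:
    """Parse a SAM-subset file.

    Returns (alignments, n_unmapped). Records with FLAG bit 0x4 are
    excluded from the list but counted. POS is converted to 0-based.
    """
    alignments: list[AlignmentRecord] = []
    n_unmapped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}: too few columns at line {lineno}")
            qname, flag_s, rname, pos_s, mapq_s, cigar = fields[:6]
            flag = int(flag_s)
            if flag & 0x4:
                n_unmapped += 1
                continue
            start = int(pos_s) - 1
            span = cigar_reference_span(cigar)
            strand = "-" if flag & 0x10 else "+"
            secondary = bool(flag & 0x100)
            alignments.append(
                AlignmentRecord(
                    read_id=qname,
                    contig_id=rname,
                    start=start,
                    end=start + span,
                    strand=strand,
                    score=int(mapq_s),
                    is_primary=not secondary,
                )
            )
    return alignments, n_unmapped


def write_alignments(
    records: Sequence[AlignmentRecord],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
) -> None:
    """Write a minimal SAM subset (match-only CIGAR, placeholder SEQ)."""
    with open(path, "w", encoding="utf-8") as fh:
        if contig_lengths:
            for cid, clen in contig_lengths.items():
                fh.write(f"@SQ\tSN:{cid}\tLN:{clen}\n")
        for rec in records:
            flag = 0
            if rec.strand == "-":
                flag |= 0x10
            if not rec.is_primary:
                flag |= 0x100
            cigar = f"{rec.reference_span}M"
            fh.write(
                f"{rec.read_id}\t{flag}\t{rec.contig_id}\t{rec.start + 1}\t"
                f"{rec.score}\t{cigar}\t*\n"
            )


# ---------------------------------------------------------------------------
# Long-read QC


def qc_filter_long_reads(
    reads: Sequence[SequenceRecord],
    min_length: int = 50,
    min_quality: float = 75,
    quality_filter: bool = True,
) -> tuple[list[SequenceRecord], int]:
    """Drop long reads shorter than ``min_length`` or scoring below
    ``min_quality``; boundary values are kept.

    Returns (kept, n_removed); counts are conserved.
    """
    kept: list[SequenceRecord] = []
    n_removed = 0
    for read in reads:
        if quality_filter:
            if read.quality is None or isinstance(read.quality, list):
                raise ConfigurationError(
                    f"read {read.id!r} lacks a read-level quality score"
                )
            ok_quality = read.quality >= min_quality
        else:
            ok_quality = True
        if len(read) >= min_length and ok_quality:
            kept.append(read)
        else:
            n_removed += 1
    return kept, n_removed
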