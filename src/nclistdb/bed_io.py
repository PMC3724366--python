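"""BED interval and position file I/O.

All coordinates follow the BED convention: 0-based, half-open
``[start, stop)``.  Only the first four BED columns (chrom, start, stop,
name) are read; strand, score and anything beyond column 4 are ignored and
never written.  Header lines starting with ``track``, ``browser`` or ``#``
are skipped on read.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "GenomicPosition",
    "BedFormatError",
    "read_bed",
    "read_positions",
    "write_bed",
]

_HEADER_PREFIXES = ("track", "browser", "#")


class BedFormatError(ValueError):
    """A malformed BED or position file line; carries the line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A labeled half-open range ``[start, stop)`` on a chromosome.

    Invariants: ``start < stop`` (empty intervals are rejected) and
    ``chrom`` is a non-empty whitespace-free token.  Labels need not be
    unique; identity inside a store is the numeric id assigned at load.
    """

    chrom: str
    start: int
    stop: int
    label: str

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if not (isinstance(self.start, int) and isinstance(self.stop, int)):
            raise TypeError("coordinates must be integers")
        if self.start < 0:
            raise ValueError(f"negative start coordinate: {self.start}")
        if self.start >= self.stop:
            raise ValueError(
                f"empty or inverted interval [{self.start}, {self.stop}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start


@dataclass(frozen=True, slots=True)
class GenomicPosition:
    """A single base-pair position (0-based) on a chromosome."""

    chrom: str
    pos: int

    def __post_init__(self) -> None:
        if not self.chrom or any(c.isspace() for c in self.chrom):
            raise ValueError(f"invalid chromosome name: {self.chrom!r}")
        if self.pos < 0:
            raise ValueError(f"negative position: {self.pos}")


def _is_header(line: str) -> bool:
    return line.startswith(_HEADER_PREFIXES)


def _parse_int(token: str, what: str, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise BedFormatError(f"non-integer {what}: {token!r}", lineno) from None


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read a BED4 file into a list of intervals, preserving file order.

    Lines must carry at least four tab-separated fields; extra columns are
    ignored.  Malformed lines (fewer than 4 fields, non-integer coordinates,
    start >= stop) raise :class:`BedFormatError` naming the offending line.
    An empty file yields an empty list.
    """
    intervals: list[GenomicInterval] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedFormatError(
                    f"expected >= 4 tab-separated fields, got {len(fields)}", lineno
                )
            chrom, start_s, stop_s, label = fields[0], fields[1], fields[2], fields[3]
            start = _parse_int(start_s, "start", lineno)
            stop = _parse_int(stop_s, "stop", lineno)
            try:
                iv = GenomicInterval(chrom, start, stop, label)
            except ValueError as exc:
                raise BedFormatError(str(exc), lineno) from None
            intervals.append(iv)
    return intervals


def read_positions(
    path: str | os.PathLike, dialect: str = "two-column"
) -> list[GenomicPosition]:
    """Read base-pair positions, either ``two-column`` (chrom<TAB>pos) or
    ``bed`` (width-1 BED intervals; the position is the start coordinate).

    Order and duplicates are preserved.  In the ``bed`` dialect a line whose
    interval is not exactly one base wide is an error.
    """
    if dialect not in ("two-column", "bed"):
        raise ValueError(f"unknown position dialect: {dialect!r}")
    positions: list[GenomicPosition] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if dialect == "two-column":
                if len(fields) < 2:
                    raise BedFormatError("expected chrom<TAB>pos", lineno)
                pos = _parse_int(fields[1], "position", lineno)
                positions.append(GenomicPosition(fields[0], pos))
            else:
                if len(fields) < 3:
                    raise BedFormatError("expected >= 3 BED fields", lineno)
                start = _parse_int(fields[1], "start", lineno)
                stop = _parse_int(fields[2], "stop", lineno)
                if stop - start != 1:
                    raise BedFormatError(
                        f"position intervals must be exactly 1 bp wide, got "
                        f"[{start}, {stop})",
                        lineno,
                    )
                positions.append(GenomicPosition(fields[0], start))
    return positions


def write_bed(
    intervals: Iterable[GenomicInterval], path: str | os.PathLike
) -> None:
    """Write intervals as 4-column tab-separated BED.

    Round-trips with :func:`read_bed` on (chrom, start, stop, label).
    """
    with open(path, "wt", encoding="utf-8") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.stop}\t{iv.label}\n")


def write_positions(
    positions: Iterable[GenomicPosition], path: str | os.PathLike
) -> None:
    """Write positions in the two-column chrom<TAB>pos format."""
    with open(path, "wt", encoding="utf-8") as fh:
        for p in positions:
            fh.write(f"{p.chrom}\t{p.pos}\n")
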