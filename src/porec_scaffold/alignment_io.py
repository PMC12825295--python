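"""Reading and filtering Pore-C fragment alignments.

A Pore-C read is a concatemer: one nanopore read reporting several genomic
fragments that were spatially proximal in the nucleus.  Aligners emit one
alignment record per fragment; records sharing a read name together describe
one multi-way contact.  This module parses those records (PAF, or a plain
TSV used by the simulator), applies the quality filters, and groups the
surviving fragments into per-read multi-way records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

__all__ = [
    "FragmentAlignment",
    "PorecRead",
    "AlignmentParseError",
    "parse_paf",
    "parse_tsv",
    "parse_alignments",
    "filter_alignments",
    "group_reads",
    "DEFAULT_MIN_ALIGN_LEN",
    "DEFAULT_MIN_MAPQ",
]

#: Fragments with aligned length <= this are discarded (strict cut).
DEFAULT_MIN_ALIGN_LEN = 100
#: Fragments with mapping quality below this are discarded (inclusive keep).
DEFAULT_MIN_MAPQ = 50


class AlignmentParseError(ValueError):
    """Raised for malformed alignment input; message carries the line number."""


@dataclass(frozen=True)
class FragmentAlignment:
    """One aligned fragment of a Pore-C read on one contig.

    Coordinates are 0-based half-open on the contig.  ``aligned_len`` is the
    contig-interval length (the span actually covered on the contig).
    """

    read_id: str
    contig_id: str
    contig_start: int
    contig_end: int
    read_start: int
    read_end: int
    strand: str
    mapq: int

    def __post_init__(self) -> None:
        if self.contig_start >= self.contig_end:
            raise ValueError(
                f"empty contig interval [{self.contig_start}, {self.contig_end}) "
                f"for read {self.read_id!r}"
            )
        if not (0 <= self.mapq <= 255):
            raise ValueError(f"mapq {self.mapq} outside [0, 255]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def aligned_len(self) -> int:
        return self.contig_end - self.contig_start


@dataclass(frozen=True)
class PorecRead:
    """All fragments of one Pore-C read, ordered along the read."""

    read_id: str
    fragments: tuple[FragmentAlignment, ...]

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("PorecRead requires at least one fragment")
        if any(f.read_id != self.read_id for f in self.fragments):
            raise ValueError("all fragments must share the read id")

    @property
    def contig_ids(self) -> frozenset[str]:
        return frozenset(f.contig_id for f in self.fragments)


def _int_field(value: str, name: str, lineno: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise AlignmentParseError(
            f"line {lineno}: non-integer {name} field {value!r}"
        ) from None


def parse_paf(path) -> Iterator[FragmentAlignment]:
    """Yield one :class:`FragmentAlignment` per mapped PAF line.

    Standard 12+ column PAF: query name/len/start/end, strand, target
    name/len/start/end, matches, block length, mapq.  Target ('*') rows are
    skipped; malformed rows raise :class:`AlignmentParseError` naming the line.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise AlignmentParseError(
                    f"line {lineno}: expected >=12 PAF columns, got {len(cols)}"
                )
            if cols[5] == "*":
                continue
            if cols[4] not in ("+", "-"):
                raise AlignmentParseError(
                    f"line {lineno}: bad strand field {cols[4]!r}"
                )
            yield FragmentAlignment(
                read_id=cols[0],
                contig_id=cols[5],
                contig_start=_int_field(cols[7], "target start", lineno),
                contig_end=_int_field(cols[8], "target end", lineno),
                read_start=_int_field(cols[2], "query start", lineno),
                read_end=_int_field(cols[3], "query end", lineno),
                strand=cols[4],
                mapq=_int_field(cols[11], "mapq", lineno),
            )


def parse_tsv(path) -> Iterator[FragmentAlignment]:
    """Yield fragments from the simulator's plain TSV dialect.

    Columns: read_id, contig_id, contig_start, contig_end, mapq, strand.
    Coordinates are 0-based half-open, matching the internal convention.
    """
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise AlignmentParseError(
                    f"line {lineno}: expected 6 TSV columns, got {len(cols)}"
                )
            start = _int_field(cols[2], "contig start", lineno)
            end = _int_field(cols[3], "contig end", lineno)
            yield FragmentAlignment(
                read_id=cols[0],
                contig_id=cols[1],
                contig_start=start,
                contig_end=end,
                read_start=0,
                read_end=end - start,
                strand=cols[5],
                mapq=_int_field(cols[4], "mapq", lineno),
            )


def parse_alignments(path) -> Iterator[FragmentAlignment]:
    """Dispatch on file extension: ``.paf`` (default) or ``.tsv``."""
    if str(path).endswith(".tsv"):
        return parse_tsv(path)
    return parse_paf(path)


def filter_alignments(
    records: Iterable[FragmentAlignment],
    min_len: int = DEFAULT_MIN_ALIGN_LEN,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> Iterator[FragmentAlignment]:
    """Keep fragments with aligned_len strictly above ``min_len`` and
    mapq at least ``min_mapq``; input order is preserved."""
    for rec in records:
        if rec.aligned_len > min_len and rec.mapq >= min_mapq:
            yield rec


def group_reads(records: Iterable[FragmentAlignment]) -> list[PorecRead]:
    """Group filtered fragments by read and drop single-contig reads.

    Reads whose fragments all map to one contig carry no inter-contig
    information and are discarded; every returned read touches >=2 distinct
    contigs.  Fragments are ordered by their position on the read.
    """
    by_read: dict[str, list[FragmentAlignment]] = {}
    for rec in records:
        by_read.setdefault(rec.read_id, []).append(rec)
    out: list[PorecRead] = []
    for read_id, frags in by_read.items():
        if len({f.contig_id for f in frags}) < 2:
            continue
        frags.sort(key=lambda f: (f.read_start, f.read_end, f.contig_id, f.contig_start))
        out.append(PorecRead(read_id=read_id, fragments=tuple(frags)))
    return out
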