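"""Genomic interval primitives shared by every pipeline stage.

All coordinates are 0-based, half-open ``[start, end)`` — the BED
convention.  A cut site at coordinate ``x`` therefore occupies the single
base ``[x, x+1)``, and two intervals that merely abut (``end == start``)
do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "read_bed",
    "write_bed",
    "merge_intervals",
    "overlap_fraction_filter",
    "overlap_any",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval with optional strand, name and score."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of '+', '-', '.', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)

    def to_bed_fields(self) -> list[str]:
        return [
            self.chrom,
            str(self.start),
            str(self.end),
            self.name,
            f"{self.score:g}",
            self.strand,
        ]


class BedParseError(ValueError):
    """Raised for a malformed BED record; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"BED line {lineno}: {message}")
        self.lineno = lineno


def read_bed(path_or_lines) -> Iterator[GenomicInterval]:
    """Stream BED3/BED6 records as :class:`GenomicInterval`.

    Accepts a path or any iterable of lines.  Missing name/score/strand
    columns default to ``"."``/``0``/``"."``.
    """
    if isinstance(path_or_lines, (str, bytes)) or hasattr(path_or_lines, "__fspath__"):
        with open(path_or_lines) as fh:
            yield from _parse_bed_lines(fh)
    else:
        yield from _parse_bed_lines(path_or_lines)


def _parse_bed_lines(lines: Iterable[str]) -> Iterator[GenomicInterval]:
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise BedParseError(lineno, f"expected >=3 tab-separated fields, got {len(fields)}")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise BedParseError(lineno, f"non-integer coordinates: {exc}") from None
        name = fields[3] if len(fields) > 3 else "."
        try:
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        except ValueError:
            raise BedParseError(lineno, f"non-numeric score {fields[4]!r}") from None
        strand = fields[5] if len(fields) > 5 else "."
        try:
            yield GenomicInterval(fields[0], start, end, strand=strand, name=name, score=score)
        except ValueError as exc:
            raise BedParseError(lineno, str(exc)) from None


def write_bed(intervals: Iterable[GenomicInterval], path) -> int:
    """Write intervals as BED6; returns the number of records written."""
    n = 0
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(iv.to_bed_fields()) + "\n")
            n += 1
    return n


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Single-linkage union of intervals overlapping by >= 1 bp.

    Output is sorted by (chrom, start) and non-overlapping.  Half-open
    abutting intervals ([a,b) and [b,c)) are NOT merged.  Strand, name and
    score are dropped (merged regions are strand-less).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    cur = None
    for iv in ivs:
        if cur is not None and iv.chrom == cur.chrom and iv.start < cur.end:
            if iv.end > cur.end:
                cur = GenomicInterval(cur.chrom, cur.start, iv.end)
        else:
            if cur is not None:
                out.append(cur)
            cur = GenomicInterval(iv.chrom, iv.start, iv.end)
    if cur is not None:
        out.append(cur)
    return out


def _trees_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def overlap_fraction_filter(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    min_frac: float,
) -> list[GenomicInterval]:
    """Keep each ``a_i`` covered >= ``min_frac`` of its length by a SINGLE
    ``b`` interval (bedtools ``intersect -f`` semantics; overlaps with
    distinct ``b`` intervals are not summed)."""
    if not (0.0 < min_frac <= 1.0):
        raise ValueError(f"min_frac must be in (0, 1], got {min_frac}")
    trees = _trees_by_chrom(b)
    kept = []
    for iv in a:
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        need = min_frac * len(iv)
        for hit in tree.overlap(iv.start, iv.end):
            if min(iv.end, hit.end) - max(iv.start, hit.begin) >= need:
                kept.append(iv)
                break
    return kept


def overlap_any(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> np.ndarray:
    """Boolean mask over ``a``: True where a_i overlaps any b by >= 1 bp."""
    trees = _trees_by_chrom(b)
    mask = np.zeros(len(a), dtype=bool)
    for i, iv in enumerate(a):
        tree = trees.get(iv.chrom)
        if tree is not None and tree.overlaps(iv.start, iv.end):
            mask[i] = True
    return mask
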