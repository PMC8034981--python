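"""Genomic interval sets: BED I/O, overlap, merging, and genome tiling.

All coordinates are 0-based half-open (BED / 10x fragments convention):
an interval covers positions ``start .. end-1`` and its length is
``end - start``. Any 1-based dialect must be converted at the reader
boundary. Chromosome names are compared by exact string equality; no
"chr" aliasing is applied (a rename map can be passed to `read_bed`).
"""

from __future__ import annotations

import gzip
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "read_bed",
    "write_bed",
    "overlaps",
    "merge_outer",
    "tile_genome",
    "overlap_matrix",
]


class BedParseError(ValueError):
    """Raised for malformed BED lines; carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One genomic region in 0-based half-open coordinates.

    Parameters
    ----------
    chrom : str
        Chromosome name (matched by exact string equality).
    start, end : int
        0-based half-open bounds; ``0 <= start < end``.
    strand : str
        "+", "-" or "." (unstranded).
    name : str, optional
        Free-text label (BED column 4).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the half-open intersection of `a` and `b` is non-empty.

    Abutting intervals (a.end == b.start) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


class _ChromIndex:
    """Sorted-start index for one chromosome with prefix max of ends.

    Query q returns every interval i with i.start < q.end and i.end > q.start,
    identical to a linear scan with `overlaps`.
    """

    def __init__(self, ivals: list[tuple[int, int, int]]):
        # ivals: (start, end, original position), sorted by (start, end)
        ivals = sorted(ivals)
        self.starts = [iv[0] for iv in ivals]
        self.ends = [iv[1] for iv in ivals]
        self.idx = [iv[2] for iv in ivals]
        self.max_end = list(np.maximum.accumulate(self.ends)) if ivals else []

    def query(self, start: int, end: int) -> list[int]:
        hits = []
        hi = bisect_right(self.starts, end - 1)  # candidates with start < end
        i = hi - 1
        while i >= 0:
            if self.max_end[i] <= start:
                break  # no interval at or left of i can reach past q.start
            if self.ends[i] > start:
                hits.append(self.idx[i])
            i -= 1
        hits.reverse()
        return hits


class IntervalSet:
    """Ordered collection of `GenomicInterval` with indexed overlap search."""

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = list(intervals)
        self._index: dict[str, _ChromIndex] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self.intervals[i]

    @property
    def is_sorted(self) -> bool:
        ivs = self.intervals
        return all(
            (ivs[i].chrom, ivs[i].start, ivs[i].end)
            <= (ivs[i + 1].chrom, ivs[i + 1].start, ivs[i + 1].end)
            for i in range(len(ivs) - 1)
        )

    def sort(self) -> "IntervalSet":
        """Return a new set sorted by (chrom, start, end)."""
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def _build_index(self) -> dict[str, _ChromIndex]:
        if self._index is None:
            per_chrom: dict[str, list[tuple[int, int, int]]] = {}
            for pos, iv in enumerate(self.intervals):
                per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, pos))
            self._index = {c: _ChromIndex(v) for c, v in per_chrom.items()}
        return self._index

    def overlapping(self, chrom: str, start: int, end: int) -> list[int]:
        """Indices of member intervals overlapping [start, end) on chrom."""
        idx = self._build_index().get(chrom)
        return idx.query(start, end) if idx is not None else []

    def expand(self, flank: int) -> "IntervalSet":
        """Symmetric expansion by `flank` bp, clipped at zero.

        Used to turn single-bp TSS anchors into TSS +/- flank windows.
        """
        return IntervalSet(
            GenomicInterval(iv.chrom, max(0, iv.start - flank), iv.end + flank,
                            iv.strand, iv.name)
            for iv in self.intervals
        )


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_bed(path, rename: dict[str, str] | None = None) -> IntervalSet:
    """Read a BED3/BED6 file (optionally gzipped) into an `IntervalSet`.

    Lines starting with "#", "track" or "browser" are skipped. Column 4
    maps to `name`; column 6 maps to `strand` ("." or absent means
    unstranded). `rename` optionally maps input chromosome names onto
    the caller's naming scheme.

    Raises
    ------
    BedParseError
        For non-integer coordinates or start >= end, naming the line.
    """
    out = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            chrom = cols[0]
            if rename:
                chrom = rename.get(chrom, chrom)
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinate") from exc
            name = cols[3] if len(cols) >= 4 and cols[3] != "." else None
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand, name))
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: {exc}") from exc
    return IntervalSet(out)


def write_bed(ivals: IntervalSet, path) -> None:
    """Write BED6 when any interval is stranded or named, else BED3."""
    bed6 = any(iv.strand != "." or iv.name is not None for iv in ivals)
    with _open_text(path, "wt") as fh:
        for iv in ivals:
            if bed6:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def merge_outer(ivals: IntervalSet) -> IntervalSet:
    """Merge overlapping intervals into their outer coordinates.

    Each output interval is the union span (min start, max end) of one
    connected component of pairwise-overlapping inputs. Abutting
    intervals are NOT merged (half-open convention: touching endpoints
    share no base). Output is disjoint and sorted. Idempotent.
    """
    srt = ivals.sort()
    merged: list[GenomicInterval] = []
    for iv in srt:
        if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom, prev.start, max(prev.end, iv.end)
            )
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return IntervalSet(merged)


def tile_genome(chrom_sizes: dict[str, int], bin_bp: int) -> IntervalSet:
    """Tile each chromosome into half-open bins of width `bin_bp`.

    The last bin of each chromosome is truncated at the chromosome end,
    so bins exactly partition the genome: ceil(length / bin_bp) bins per
    chromosome.
    """
    if bin_bp <= 0:
        raise ValueError(f"bin_bp must be positive, got {bin_bp}")
    out = []
    for chrom, length in chrom_sizes.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom} has non-positive length {length}")
        for start in range(0, length, bin_bp):
            out.append(GenomicInterval(chrom, start, min(start + bin_bp, length)))
    return IntervalSet(out)


def overlap_matrix(sets: list[IntervalSet], master: IntervalSet) -> np.ndarray:
    """Binary matrix (master interval x set): 1 iff any interval of the
    set overlaps the master interval.

    Used to compare peak calls across cell types against a merged
    master peak set.
    """
    mat = np.zeros((len(master), len(sets)), dtype=np.int8)
    for s, ivset in enumerate(sets):
        for iv in ivset:
            for m in master.overlapping(iv.chrom, iv.start, iv.end):
                mat[m, s] = 1
    return mat
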