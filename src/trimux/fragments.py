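"""ATAC fragment model, fragments.tsv I/O, collapsing, and overlap counting.

A fragment file is the 10x dialect: tab-separated ``chrom  start  end
barcode  count[  strand]`` with 0-based half-open coordinates, plain or
gzip-compressed. Single-end data (e.g. ICICLE) carries a strand column;
paired-end fragments are unstranded. No Tn5 +4/-5 shift is applied at
construction time — shifts happen only inside pileup operations — so a
stored file stays equal to upstream tool output.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from scipy import sparse

from trimux.intervals import IntervalSet

__all__ = [
    "FragmentRecord",
    "AlignedRead",
    "FragmentMatrix",
    "collapse_fragments",
    "read_fragments",
    "write_fragments",
    "count_overlaps",
    "binarize",
]


class FragmentParseError(ValueError):
    """Raised for malformed fragment lines; carries the 1-based line number."""


@dataclass(frozen=True, order=True)
class FragmentRecord:
    """One deduplicated Tn5 fragment."""

    chrom: str
    start: int
    end: int
    barcode: str
    dup_count: int = 1
    strand: str = "."

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")
        if self.dup_count < 1:
            raise ValueError(f"dup_count must be >= 1, got {self.dup_count}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """Minimal view of one aligned single-end read."""

    chrom: str
    pos: int
    length: int
    strand: str
    barcode: str
    align_score: int

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("aligned length must be positive")


def collapse_fragments(
    reads: Iterable[AlignedRead], min_score: int = 30
) -> list[FragmentRecord]:
    """Deduplicate aligned reads into fragments.

    Reads with alignment score below `min_score` are dropped. Each
    surviving read spans [pos, pos+length); reads sharing (chrom, start,
    end, barcode, strand) collapse into one record whose dup_count is
    the group size. For single-end data a + and a - read at identical
    coordinates are distinct transposition events, hence strand is part
    of the duplicate key. Output is sorted by (chrom, start, end,
    barcode, strand).
    """
    groups: dict[tuple, int] = {}
    for r in reads:
        if r.align_score < min_score:
            continue
        key = (r.chrom, r.pos, r.pos + r.length, r.barcode, r.strand)
        groups[key] = groups.get(key, 0) + 1
    return [
        FragmentRecord(c, s, e, bc, n, strand)
        for (c, s, e, bc, strand), n in sorted(groups.items())
    ]


def _open_text(path, mode="rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(path) -> Iterator[FragmentRecord]:
    """Stream records from a fragments.tsv(.gz) file.

    Accepts 4-6 tab-separated columns; column 5 (duplicate count)
    defaults to 1, column 6 (strand) to unstranded.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FragmentParseError(f"line {lineno}: fewer than 4 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
                dup = int(cols[4]) if len(cols) >= 5 else 1
            except ValueError as exc:
                raise FragmentParseError(f"line {lineno}: {exc}") from exc
            strand = cols[5] if len(cols) >= 6 and cols[5] in ("+", "-") else "."
            try:
                yield FragmentRecord(cols[0], start, end, cols[3], dup, strand)
            except ValueError as exc:
                raise FragmentParseError(f"line {lineno}: {exc}") from exc


def write_fragments(records: Iterable[FragmentRecord], path) -> None:
    """Write records in the 10x dialect; strand column only if any record
    is stranded (round-trips read_fragments output field-identically)."""
    records = list(records)
    stranded = any(r.strand != "." for r in records)
    with _open_text(path, "wt") as fh:
        for r in records:
            base = f"{r.chrom}\t{r.start}\t{r.end}\t{r.barcode}\t{r.dup_count}"
            fh.write(base + (f"\t{r.strand}\n" if stranded else "\n"))


@dataclass
class FragmentMatrix:
    """Sparse barcode x feature overlap-count matrix."""

    matrix: sparse.csr_matrix
    barcodes: list[str]
    features: IntervalSet
    binarized: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def to_mtx(self, prefix) -> None:
        """MatrixMarket triplet export with row/column name sidecars."""
        from scipy.io import mmwrite

        mmwrite(f"{prefix}.mtx", self.matrix)
        with open(f"{prefix}.barcodes.txt", "w") as fh:
            fh.write("\n".join(self.barcodes) + "\n")
        with open(f"{prefix}.features.bed", "w") as fh:
            for iv in self.features:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def count_overlaps(
    frags: Iterable[FragmentRecord], features: IntervalSet
) -> FragmentMatrix:
    """Count, per barcode, fragments overlapping each feature interval.

    Each fragment contributes once to every feature it overlaps
    (half-open intersection), regardless of its duplicate count.
    """
    barcode_ix: dict[str, int] = {}
    rows, cols = [], []
    for frag in frags:
        hits = features.overlapping(frag.chrom, frag.start, frag.end)
        if not hits:
            # still register the barcode so empty rows are representable
            barcode_ix.setdefault(frag.barcode, len(barcode_ix))
            continue
        r = barcode_ix.setdefault(frag.barcode, len(barcode_ix))
        for h in hits:
            rows.append(r)
            cols.append(h)
    mat = sparse.coo_matrix(
        (np.ones(len(rows), dtype=np.int64), (rows, cols)),
        shape=(len(barcode_ix), len(features)),
    ).tocsr()
    return FragmentMatrix(mat, list(barcode_ix), features)


def binarize(m: FragmentMatrix) -> FragmentMatrix:
    """Clip counts to presence/absence {0, 1}. Idempotent."""
    b = m.matrix.copy()
    b.data = np.minimum(b.data, 1)
    return FragmentMatrix(b, list(m.barcodes), m.features, binarized=True)
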