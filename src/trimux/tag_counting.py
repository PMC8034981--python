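"""ADT tag counting from raw paired reads.

Re-implements the BarCounter algorithm: read 1 carries a 16-nt cell
barcode followed by a 12-nt UMI; read 2 carries the antibody tag
barcode at its 5' end. Cell barcodes not on the whitelist are rescued
by single-base (Hamming-1) correction; in the default ``quality_gated``
mode the mismatching base must have a Phred quality below 20. Tag
barcodes allow one mismatch anywhere (TotalSeq-A barcodes are mutually
Hamming >= 3 apart, so a single substitution is unambiguous). UMIs that
are unique within their assigned (cell barcode, antibody) pair are
counted; final counts are written per cell barcode as CSV.
"""

from __future__ import annotations

import csv
import gzip
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "ReadPair",
    "Whitelist",
    "TagList",
    "TagCountMatrix",
    "correct_cell_barcode",
    "match_tag",
    "count_tags",
    "read_fastq_pairs",
    "REJECT",
]

_BASES = "ACGT"
QUALITY_GATE = 20  # Phred score below which a basecall is "low quality"

#: Sentinel returned when a barcode cannot be corrected / a tag not matched.
REJECT = None


@dataclass(frozen=True)
class ReadPair:
    """One ADT read pair: sequences plus integer Phred qualities."""

    r1_seq: str
    r1_qual: tuple[int, ...]
    r2_seq: str
    r2_qual: tuple[int, ...]

    def __post_init__(self):
        if len(self.r1_seq) != len(self.r1_qual) or len(self.r2_seq) != len(self.r2_qual):
            raise ValueError("sequence and quality lengths differ")


class Whitelist:
    """Set of valid cell barcodes, all the same length (default 16 nt)."""

    def __init__(self, barcodes: Iterable[str]):
        self.barcodes = frozenset(b.upper() for b in barcodes)
        if not self.barcodes:
            raise ValueError("empty whitelist")
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcodes of mixed lengths {sorted(lengths)}")
        self.length = lengths.pop()
        bad = [b for b in self.barcodes if set(b) - set(_BASES)]
        if bad:
            raise ValueError(f"whitelist contains non-ACGT barcodes, e.g. {bad[0]}")

    def __contains__(self, seq: str) -> bool:
        return seq in self.barcodes

    def __len__(self) -> int:
        return len(self.barcodes)

    @classmethod
    def from_file(cls, path) -> "Whitelist":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            return cls(line.strip() for line in fh if line.strip())


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("length mismatch")
    return sum(x != y for x, y in zip(a, b))


class TagList:
    """Antibody name -> tag barcode map with uniform barcode length.

    The minimum pairwise Hamming distance is computed at load time; a
    warning is emitted when it drops below 3 (one allowed mismatch then
    no longer guarantees unambiguous assignment).
    """

    def __init__(self, entries: dict[str, str]):
        if not entries:
            raise ValueError("empty taglist")
        self.entries = {name: seq.upper() for name, seq in entries.items()}
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) != 1:
            raise ValueError(f"tag barcodes of mixed lengths {sorted(lengths)}")
        self.length = lengths.pop()
        seqs = list(self.entries.values())
        if len(set(seqs)) != len(seqs):
            raise ValueError("duplicate tag barcode sequences")
        self.min_pairwise_distance = min(
            (hamming(a, b) for i, a in enumerate(seqs) for b in seqs[i + 1:]),
            default=self.length,
        )
        if self.min_pairwise_distance < 3:
            warnings.warn(
                f"taglist minimum pairwise Hamming distance is "
                f"{self.min_pairwise_distance} < 3; single-mismatch tag "
                "assignment may be ambiguous",
                stacklevel=2,
            )
        self._exact = {seq: name for name, seq in self.entries.items()}

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path) -> "TagList":
        """Load a two-column CSV of ``name,sequence`` (no header required)."""
        entries = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                name, seq = row[0].strip(), row[1].strip().upper()
                if set(seq) - set(_BASES):
                    continue  # header row or malformed sequence
                entries[name] = seq
        return cls(entries)


def correct_cell_barcode(
    seq: str,
    quals: Iterable[int],
    wl: Whitelist,
    mode: str = "quality_gated",
) -> str | None:
    """Correct one cell barcode against the whitelist, or REJECT (None).

    Exact whitelist members pass through unchanged. Otherwise all
    Hamming-1 neighbours on the whitelist are enumerated (<= 3 x length
    candidates, no precomputed neighbour index).

    mode="quality_gated" (ADT rule): a candidate qualifies only if the
    mismatching position has quality < 20; accepted iff exactly one
    candidate qualifies.

    mode="lowest_quality_position" (ICICLE ATAC rule): any single
    mismatch is allowed; with several candidates the one mismatching at
    the lowest-quality position wins; unresolved ties are rejected.
    """
    seq = seq.upper()
    if len(seq) != wl.length:
        raise ValueError(f"barcode length {len(seq)} != whitelist length {wl.length}")
    if seq in wl:
        return seq
    quals = tuple(quals)
    if len(quals) < wl.length:
        raise ValueError("quality string shorter than barcode")

    candidates: list[tuple[int, str]] = []  # (mismatch position, whitelist barcode)
    for pos, orig in enumerate(seq):
        prefix, suffix = seq[:pos], seq[pos + 1:]
        for base in _BASES:
            if base == orig:
                continue
            cand = prefix + base + suffix
            if cand in wl:
                candidates.append((pos, cand))

    if not candidates:
        return REJECT
    if mode == "quality_gated":
        qualifying = [c for c in candidates if quals[c[0]] < QUALITY_GATE]
        if len(qualifying) == 1:
            return qualifying[0][1]
        return REJECT
    if mode == "lowest_quality_position":
        if len(candidates) == 1:
            return candidates[0][1]
        best_q = min(quals[pos] for pos, _ in candidates)
        best = [c for c in candidates if quals[c[0]] == best_q]
        if len(best) == 1:
            return best[0][1]
        return REJECT
    raise ValueError(f"unknown mode {mode!r}")


def match_tag(seq: str, tags: TagList, max_mismatch: int = 1) -> str | None:
    """Assign a read-2 prefix to an antibody, allowing one mismatch.

    Exact match wins; else the unique tag at Hamming distance
    <= max_mismatch; None when no tag or several tags qualify.
    """
    seq = seq[: tags.length].upper()
    if len(seq) < tags.length:
        return None
    name = tags._exact.get(seq)
    if name is not None:
        return name
    if max_mismatch == 0:
        return None
    hits = [
        name
        for name, tag in tags.entries.items()
        if hamming(seq, tag) <= max_mismatch
    ]
    return hits[0] if len(hits) == 1 else None


@dataclass
class TagCountMatrix:
    """Cell barcode x antibody UMI count matrix with a run report.

    `counts` rows are cell barcodes, columns antibody names; values are
    the number of distinct UMIs observed for that (cell, antibody).
    Rows with zero total are never emitted.
    """

    counts: pd.DataFrame
    report: dict = field(default_factory=dict)

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def to_csv(self, path) -> None:
        """BarCounter-style output: cell_barcode,total,<ab1>,<ab2>,..."""
        out = self.counts.copy()
        out.insert(0, "total", self.totals)
        out.index.name = "cell_barcode"
        out.to_csv(path)

    def write_report(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.report, fh, indent=2)


def read_fastq_pairs(r1_path, r2_path) -> Iterator[ReadPair]:
    """Stream read pairs from two (optionally gzipped) FASTQ files."""

    def _open(path):
        return gzip.open(path, "rt") if str(path).endswith(".gz") else open(path)

    with _open(r1_path) as fh1, _open(r2_path) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        for (t1, s1, q1), (t2, s2, q2) in zip(it1, it2):
            yield ReadPair(
                s1,
                tuple(ord(c) - 33 for c in q1),
                s2,
                tuple(ord(c) - 33 for c in q2),
            )


def count_tags(
    reads: Iterable[ReadPair],
    wl: Whitelist,
    tags: TagList,
    barcode_len: int = 16,
    umi_len: int = 12,
    mode: str = "quality_gated",
    tag_offset: int = 0,
) -> TagCountMatrix:
    """Count unique UMIs per (corrected cell barcode, antibody).

    Each read pair passes through cell-barcode correction and tag
    matching; survivors contribute their (barcode, antibody, UMI)
    triple, and the count for a (cell, antibody) pair is the number of
    distinct UMIs. UMIs containing N are dropped (they cannot be
    deduplicated reliably). The run report tallies every exclusion.
    `tag_offset` skips a fixed number of read-2 bases before the tag
    barcode for chemistry variants.
    """
    umis: dict[tuple[str, str], set[str]] = {}
    report = {
        "total_reads": 0,
        "short_read1": 0,
        "umi_with_N": 0,
        "barcode_rejected": 0,
        "tag_unassigned": 0,
        "counted": 0,
    }
    for pair in reads:
        report["total_reads"] += 1
        if len(pair.r1_seq) < barcode_len + umi_len:
            report["short_read1"] += 1
            continue
        umi = pair.r1_seq[barcode_len: barcode_len + umi_len].upper()
        if "N" in umi:
            report["umi_with_N"] += 1
            continue
        bc = correct_cell_barcode(
            pair.r1_seq[:barcode_len], pair.r1_qual[:barcode_len], wl, mode=mode
        )
        if bc is REJECT:
            report["barcode_rejected"] += 1
            continue
        ab = match_tag(pair.r2_seq[tag_offset:], tags)
        if ab is None:
            report["tag_unassigned"] += 1
            continue
        umis.setdefault((bc, ab), set()).add(umi)
        report["counted"] += 1

    cells = sorted({bc for bc, _ in umis})
    ab_names = list(tags.entries)
    counts = pd.DataFrame(0, index=cells, columns=ab_names, dtype=int)
    for (bc, ab), umi_set in umis.items():
        counts.at[bc, ab] = len(umi_set)
    counts = counts[counts.sum(axis=1) > 0]
    report["cells_emitted"] = int(counts.shape[0])
    return TagCountMatrix(counts=counts, report=report)
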