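"""Per-barcode ATAC quality control and insertion-site pileups.

Metrics follow the denominator conventions of the source pipelines:
the mitochondrial fraction and duplicate structure are fractions of
total fragments (duplicates included), while FRIP, FRITSS and the DHS
fraction are fractions of unique (deduplicated) fragments. Filtering
uses strict inequalities, so a barcode at exactly the threshold fails.

Pileups model Tn5 transposition: each fragment end is an insertion
event whose target-site duplication (TSD) spans 9 bp. The Tn5
footprint is the 29 bp window of accessible DNA around one insertion
(9 bp TSD plus 10 bp on either side). TSD center positions are
obtained by shifting +4 bp from the fragment 5' end and -5 bp from the
3' end (the last covered base, since `end` is exclusive).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from trimux.fragments import FragmentRecord
from trimux.intervals import IntervalSet

__all__ = [
    "BarcodeQC",
    "QCThresholds",
    "PileupProfile",
    "compute_barcode_qc",
    "filter_barcodes",
    "fragment_length_histogram",
    "tss_footprint_pileup",
    "tsd_center_pileup",
    "MITO_CHROMS",
]

MITO_CHROMS = frozenset({"chrM", "MT"})


@dataclass
class BarcodeQC:
    """QC metric bundle for one cell barcode."""

    barcode: str
    n_total: int
    n_unique: int
    frac_mito: float
    frip: float
    fritss: float
    frac_dhs: float
    passed: bool | None = None


@dataclass(frozen=True)
class QCThresholds:
    """Pass thresholds (all strict >) for barcode filtering.

    Presets: ``standard`` for droplet scATAC (1000 unique fragments,
    FRIP/FRITSS 0.2, DHS 0.5), ``icicle`` for the lower-depth
    plate-based chemistry (500, FRIP 0.65), and ``tea_atac`` for the
    trimodal assay (2500 unique fragments).
    """

    min_unique: int = 1000
    min_frip: float = 0.2
    min_fritss: float = 0.2
    min_dhs: float = 0.5
    preset: str = "standard"

    @classmethod
    def from_preset(cls, name: str) -> "QCThresholds":
        presets = {
            "standard": (1000, 0.2, 0.2, 0.5),
            "icicle": (500, 0.65, 0.2, 0.5),
            "tea_atac": (2500, 0.2, 0.2, 0.5),
        }
        if name not in presets:
            raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
        u, p, t, d = presets[name]
        return cls(u, p, t, d, preset=name)


def compute_barcode_qc(
    frags: Iterable[FragmentRecord],
    peaks: IntervalSet,
    tss: IntervalSet,
    dhs: IntervalSet,
    mito_chroms: frozenset[str] = MITO_CHROMS,
) -> dict[str, BarcodeQC]:
    """Compute per-barcode QC metrics from deduplicated fragments.

    `tss` must already be expanded to windows (e.g. +/-2 kb around the
    start site; see ``IntervalSet.expand``). A fragment overlapping at
    least one interval of a reference set counts once toward that set's
    numerator. Barcodes with no fragments are absent; a barcode whose
    records are all invalid never arises because records validate on
    construction.
    """
    stats: dict[str, dict[str, int]] = {}
    for f in frags:
        s = stats.setdefault(
            f.barcode,
            {"total": 0, "unique": 0, "mito": 0, "peak": 0, "tss": 0, "dhs": 0},
        )
        s["total"] += f.dup_count
        s["unique"] += 1
        if f.chrom in mito_chroms:
            s["mito"] += f.dup_count
        if peaks.overlapping(f.chrom, f.start, f.end):
            s["peak"] += 1
        if tss.overlapping(f.chrom, f.start, f.end):
            s["tss"] += 1
        if dhs.overlapping(f.chrom, f.start, f.end):
            s["dhs"] += 1

    out = {}
    for bc, s in stats.items():
        if s["unique"] == 0:
            continue
        out[bc] = BarcodeQC(
            barcode=bc,
            n_total=s["total"],
            n_unique=s["unique"],
            frac_mito=s["mito"] / s["total"],
            frip=s["peak"] / s["unique"],
            fritss=s["tss"] / s["unique"],
            frac_dhs=s["dhs"] / s["unique"],
        )
    return out


def filter_barcodes(
    qc: Mapping[str, BarcodeQC], th: QCThresholds
) -> tuple[set[str], dict[str, list[str]]]:
    """Split barcodes into a pass set and a fail map with reasons.

    All comparisons are strict: a barcode with exactly `min_unique`
    unique fragments (or FRIP exactly at the threshold) fails. Every
    violated criterion is listed, and each BarcodeQC's `passed` flag is
    set in place.
    """
    passed: set[str] = set()
    failed: dict[str, list[str]] = {}
    for bc, q in qc.items():
        reasons = []
        if not q.n_unique > th.min_unique:
            reasons.append(f"n_unique {q.n_unique} <= {th.min_unique}")
        if not q.frip > th.min_frip:
            reasons.append(f"frip {q.frip:.4f} <= {th.min_frip}")
        if not q.fritss > th.min_fritss:
            reasons.append(f"fritss {q.fritss:.4f} <= {th.min_fritss}")
        if not q.frac_dhs > th.min_dhs:
            reasons.append(f"frac_dhs {q.frac_dhs:.4f} <= {th.min_dhs}")
        q.passed = not reasons
        if reasons:
            failed[bc] = reasons
        else:
            passed.add(bc)
    return passed, failed


def qc_table(qc: Mapping[str, BarcodeQC]) -> pd.DataFrame:
    """Per-barcode QC metrics as a DataFrame (CSV-exportable)."""
    return pd.DataFrame(
        [
            {
                "barcode": q.barcode,
                "n_total": q.n_total,
                "n_unique": q.n_unique,
                "frac_mito": q.frac_mito,
                "frip": q.frip,
                "fritss": q.fritss,
                "frac_dhs": q.frac_dhs,
                "passed": q.passed,
            }
            for q in qc.values()
        ]
    ).set_index("barcode")


def fragment_length_histogram(
    frags: Iterable[FragmentRecord],
    groups: Mapping[str, str] | None = None,
    max_len: int = 1000,
) -> pd.DataFrame:
    """Fragment-length counts per group (columns), lengths 1..max_len.

    `groups` maps barcode -> group label; unmapped barcodes are skipped
    when a mapping is given, otherwise all fragments pool into "all".
    Lengths above `max_len` land in the overflow row labelled
    ``max_len + 1``.
    """
    labels = sorted(set(groups.values())) if groups else ["all"]
    hist = {g: np.zeros(max_len + 1, dtype=np.int64) for g in labels}
    for f in frags:
        if groups is None:
            g = "all"
        else:
            g = groups.get(f.barcode)
            if g is None:
                continue
        hist[g][min(f.length - 1, max_len)] += 1
    return pd.DataFrame(hist, index=pd.RangeIndex(1, max_len + 2, name="length"))


@dataclass
class PileupProfile:
    """Aggregate signal at offsets relative to a set of anchors."""

    offsets: np.ndarray
    counts: np.ndarray
    anchor_kind: str
    n_anchors: int

    def to_tsv(self, path) -> None:
        pd.DataFrame({"offset": self.offsets, "count": self.counts}).to_csv(
            path, sep="\t", index=False
        )


def footprint_interval(
    insertion: int, footprint_flank: int = 10, tsd_len: int = 9
) -> tuple[int, int]:
    """Half-open genomic span of the accessible footprint around one
    TSD center position; width = tsd_len + 2*footprint_flank (29 bp for
    defaults)."""
    half = (tsd_len - 1) // 2 + footprint_flank
    return insertion - half, insertion - half + tsd_len + 2 * footprint_flank


def _group_fragments_by_chrom(frags):
    by_chrom: dict[str, list[FragmentRecord]] = {}
    for f in frags:
        by_chrom.setdefault(f.chrom, []).append(f)
    return by_chrom


def tss_footprint_pileup(
    frags: Iterable[FragmentRecord],
    tss_points: IntervalSet,
    window: int = 2000,
    mode: str = "footprint",
    footprint_flank: int = 10,
    tsd_len: int = 9,
    shift_5p: int = 4,
    shift_3p: int = -5,
) -> PileupProfile:
    """Aggregate Tn5 signal around single-bp stranded TSS anchors.

    mode="footprint": each fragment end is an insertion whose TSD
    center (5' end + shift_5p, or last base + shift_3p) anchors a
    contiguous accessible region of ``tsd_len + 2*footprint_flank`` bp;
    that region's in-window bases are added to the profile.
    mode="fragment_coverage": per-base fragment overlap counts.
    Offsets are relative to the anchor and strand-flipped for "-"
    anchors; the profile spans -window..+window inclusive.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if mode not in ("footprint", "fragment_coverage"):
        raise ValueError(f"unknown mode {mode!r}")
    width = 2 * window + 1
    counts = np.zeros(width, dtype=np.int64)
    by_chrom = _group_fragments_by_chrom(frags)

    n_anchors = 0
    for anchor in tss_points:
        n_anchors += 1
        pos = anchor.start
        flip = anchor.strand == "-"
        lo, hi = pos - window, pos + window + 1  # genomic span covered
        for f in by_chrom.get(anchor.chrom, ()):
            if mode == "fragment_coverage":
                spans = [(f.start, f.end)]
            else:
                spans = [
                    footprint_interval(f.start + shift_5p, footprint_flank, tsd_len),
                    footprint_interval((f.end - 1) + shift_3p, footprint_flank, tsd_len),
                ]
            for s, e in spans:
                s, e = max(s, lo), min(e, hi)
                if s >= e:
                    continue
                off_lo, off_hi = s - pos, e - pos  # offsets in [-w, w+1)
                if flip:
                    # offset o -> -o; half-open [off_lo, off_hi) -> [1-off_hi, 1-off_lo)
                    off_lo, off_hi = 1 - off_hi, 1 - off_lo
                counts[off_lo + window: off_hi + window] += 1
    return PileupProfile(
        offsets=np.arange(-window, window + 1),
        counts=counts,
        anchor_kind="TSS",
        n_anchors=n_anchors,
    )


def tsd_center_pileup(
    frags: Iterable[FragmentRecord],
    motif_regions: IntervalSet,
    shift_5p: int = 4,
    shift_3p: int = -5,
) -> PileupProfile:
    """Tally TSD center positions across uniform stranded motif windows.

    Each fragment [s, e) yields two TSD centers: ``s + shift_5p`` and
    ``(e - 1) + shift_3p``. Every center falling inside a region is
    counted at its offset from the region center, strand-flipped for
    "-" motifs. All regions must share one width (they are windows of
    fixed extent centered on motif middles).
    """
    widths = {len(r) for r in motif_regions}
    if len(widths) > 1:
        raise ValueError(f"motif regions of mixed widths {sorted(widths)}")
    if not widths:
        return PileupProfile(np.array([], dtype=int), np.array([], dtype=np.int64),
                             "motif_center", 0)
    width = widths.pop()
    half = width // 2
    offsets = np.arange(-half, width - half)
    counts = np.zeros(width, dtype=np.int64)

    by_chrom = _group_fragments_by_chrom(frags)
    for region in motif_regions:
        center = region.start + half
        flip = region.strand == "-"
        for f in by_chrom.get(region.chrom, ()):
            for point in (f.start + shift_5p, (f.end - 1) + shift_3p):
                if region.start <= point < region.end:
                    off = center - point if flip else point - center
                    ix = off + half
                    if 0 <= ix < width:
                        counts[ix] += 1
    return PileupProfile(offsets=offsets, counts=counts,
                         anchor_kind="motif_center", n_anchors=len(motif_regions))
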