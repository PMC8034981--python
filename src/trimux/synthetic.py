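"""Synthetic fixture generators for every pipeline stage.

All generators are pure functions of (seed, parameters): identical
inputs give byte-identical files. Fragment fixtures live on a small
artificial genome (three 10 Mb chromosomes plus a short mitochondrial
contig); no real genome or download is needed. Quality strings are
deterministic — planted mutations carry Phred 10, everything else 37 —
so the quality-gated barcode-correction path behaves predictably.

These fixtures emulate the structure of real libraries (barcode and
tag grammar, peak/TSS enrichment, sub-nucleosomal vs mononucleosomal
fragment lengths, modality-specific cluster separation) but not
sequence content, genome composition, or chromatin biology.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from trimux.fragments import FragmentRecord, write_fragments
from trimux.intervals import GenomicInterval, IntervalSet, write_bed

__all__ = [
    "SimTruth",
    "random_barcodes",
    "gen_adt_reads",
    "gen_fragments",
    "gen_accessibility_matrix",
    "gen_trimodal_embeddings",
    "GENOME",
]

_BASES = np.array(list("ACGT"))

#: Artificial genome used by all fragment fixtures.
GENOME = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000, "chrM": 16_000}

QUAL_HIGH = 37
QUAL_LOW = 10  # planted mutations; below the <20 correction gate


@dataclass
class SimTruth:
    """Ground truth accompanying one generated fixture."""

    seed: int
    params: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {"seed": self.seed, "params": self.params}
        for k, v in self.tables.items():
            if isinstance(v, pd.DataFrame):
                payload[k] = v.to_dict()
            elif isinstance(v, (list, dict)):
                payload[k] = v
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)


def random_barcodes(n: int, length: int, rng: np.random.Generator,
                    min_distance: int = 3, max_tries: int = 200) -> list[str]:
    """Distinct random barcodes with pairwise Hamming >= min_distance.

    Random k-mers of length >= 15 are almost always far apart; offending
    draws are resampled. Intended for fixture-scale sets (<= a few
    thousand barcodes).
    """
    codes: list[np.ndarray] = []
    while len(codes) < n:
        for _ in range(max_tries):
            cand = rng.integers(0, 4, size=length)
            if all(int(np.sum(cand != c)) >= min_distance for c in codes):
                codes.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place barcode {len(codes) + 1} at distance "
                f"{min_distance} in {max_tries} tries"
            )
    return ["".join(_BASES[c]) for c in codes]


def _mutate_one(seq: str, pos: int, rng: np.random.Generator) -> str:
    alt = [b for b in "ACGT" if b != seq[pos]]
    return seq[:pos] + alt[rng.integers(0, 3)] + seq[pos + 1:]


def gen_adt_reads(
    outdir,
    n_cells: int = 100,
    n_tags: int = 46,
    reads_per_cell: int = 100,
    dup_rate: float = 0.3,
    error_rate: float = 0.05,
    barcode_len: int = 16,
    umi_len: int = 12,
    tag_len: int = 15,
    seed: int = 0,
) -> SimTruth:
    """Generate a paired ADT FASTQ fixture with whitelist and taglist.

    Read 1 is barcode + UMI; read 2 is the tag barcode. With
    probability `dup_rate` a read re-uses an earlier (tag, UMI) pair of
    its cell (a PCR duplicate); with probability `error_rate` a single
    barcode base is substituted and given quality 10 (< 20), and
    independently, with the same rate, a single tag base is substituted.
    Whitelist and taglist have pairwise Hamming distance >= 3, so every
    planted single-base error is uniquely correctable and the truth UMI
    matrix equals what a perfect counter recovers.

    Writes r1.fastq.gz, r2.fastq.gz, whitelist.txt, taglist.csv and
    truth.json under `outdir`; returns the SimTruth (with the truth
    count matrix under ``tables["counts"]``).
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    whitelist = random_barcodes(n_cells, barcode_len, rng)
    tag_seqs = random_barcodes(n_tags, tag_len, rng)
    tag_names = [f"AB{i:03d}" for i in range(n_tags)]

    truth = np.zeros((n_cells, n_tags), dtype=int)
    r1_lines, r2_lines = [], []
    read_no = 0
    for ci, bc in enumerate(whitelist):
        seen: list[tuple[int, str]] = []  # planted (tag index, umi) pairs
        for _ in range(reads_per_cell):
            if seen and rng.random() < dup_rate:
                ti, umi = seen[rng.integers(0, len(seen))]
            else:
                ti = int(rng.integers(0, n_tags))
                umi = "".join(_BASES[rng.integers(0, 4, size=umi_len)])
                if (ti, umi) not in seen:
                    truth[ci, ti] += 1
                seen.append((ti, umi))

            r1 = bc + umi
            q1 = [QUAL_HIGH] * len(r1)
            if rng.random() < error_rate:
                pos = int(rng.integers(0, barcode_len))
                r1 = _mutate_one(r1, pos, rng)
                q1[pos] = QUAL_LOW
            r2 = tag_seqs[ti]
            q2 = [QUAL_HIGH] * tag_len
            if rng.random() < error_rate:
                pos = int(rng.integers(0, tag_len))
                r2 = _mutate_one(r2, pos, rng)
                q2[pos] = QUAL_LOW
            read_no += 1
            name = f"read{read_no}"
            r1_lines.append(
                f"@{name}\n{r1}\n+\n{''.join(chr(q + 33) for q in q1)}\n"
            )
            r2_lines.append(
                f"@{name}\n{r2}\n+\n{''.join(chr(q + 33) for q in q2)}\n"
            )

    with gzip.open(outdir / "r1.fastq.gz", "wt") as fh:
        fh.write("".join(r1_lines))
    with gzip.open(outdir / "r2.fastq.gz", "wt") as fh:
        fh.write("".join(r2_lines))
    with open(outdir / "whitelist.txt", "w") as fh:
        fh.write("\n".join(whitelist) + "\n")
    with open(outdir / "taglist.csv", "w") as fh:
        fh.writelines(f"{n},{s}\n" for n, s in zip(tag_names, tag_seqs))

    counts = pd.DataFrame(truth, index=whitelist, columns=tag_names)
    st = SimTruth(
        seed=seed,
        params={
            "n_cells": n_cells, "n_tags": n_tags,
            "reads_per_cell": reads_per_cell, "dup_rate": dup_rate,
            "error_rate": error_rate,
        },
        tables={"counts": counts, "whitelist": whitelist,
                "tag_names": tag_names, "tag_seqs": tag_seqs},
    )
    st.to_json(outdir / "truth.json")
    return st


def _sample_length(rng: np.random.Generator, nucleosomal_fraction: float) -> int:
    """Sub-nucleosomal (~80 bp) / mononucleosomal (~180 bp) mixture."""
    if rng.random() < nucleosomal_fraction:
        return max(10, int(rng.normal(180, 20)))
    return max(10, int(rng.normal(80, 15)))


def gen_fragments(
    outdir,
    n_cells: int = 50,
    n_noise: int = 50,
    frags_per_cell: int = 2000,
    frags_per_noise: int = 200,
    frip_true: float = 0.55,
    fritss_true: float = 0.25,
    noise_frip: float = 0.1,
    nucleosomal_fraction: float = 0.25,
    mito_rate: float = 0.02,
    n_peaks: int = 200,
    n_tss: int = 60,
    seed: int = 0,
):
    """Generate a fragments.tsv.gz fixture with peak/TSS/DHS BEDs.

    Two barcode classes emulate real libraries: cell-like barcodes with
    `frags_per_cell` fragments placed into peaks at rate `frip_true`
    and TSS windows at rate `fritss_true`, and noise-like barcodes with
    few fragments and `noise_frip` peak rate — so QC filtering can
    separate them. Peaks (500 bp) and TSS windows (+/-2 kb around a
    stranded point) are disjoint; the DHS set is their union, making
    the planted DHS fraction frip + fritss. A `mito_rate` fraction of
    fragments lands on chrM. Fragment lengths mix ~80 bp open-chromatin
    and ~180 bp mononucleosomal components.

    Returns (paths dict, SimTruth). Truth tables carry per-barcode
    class labels and planted rates.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    chroms = [c for c in GENOME if c != "chrM"]

    # disjoint peaks and TSS windows on a coarse grid
    slots = []
    for chrom in chroms:
        slots += [(chrom, s) for s in range(50_000, GENOME[chrom] - 50_000, 25_000)]
    slot_ix = rng.choice(len(slots), size=n_peaks + n_tss, replace=False)
    peak_ivs, tss_points = [], []
    for j, si in enumerate(slot_ix):
        chrom, s = slots[si]
        if j < n_peaks:
            peak_ivs.append(GenomicInterval(chrom, s, s + 500))
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            tss_points.append(GenomicInterval(chrom, s, s + 1, strand))
    peaks = IntervalSet(peak_ivs).sort()
    tss_pt = IntervalSet(tss_points).sort()
    tss_windows = tss_pt.expand(2000)
    dhs = IntervalSet(list(peaks) + list(tss_windows)).sort()

    barcodes = random_barcodes(n_cells + n_noise, 16, np.random.default_rng(seed + 1))
    classes = ["cell"] * n_cells + ["noise"] * n_noise

    records = []
    for bc, cls in zip(barcodes, classes):
        n_frags = frags_per_cell if cls == "cell" else frags_per_noise
        p_peak = frip_true if cls == "cell" else noise_frip
        p_tss = fritss_true if cls == "cell" else 0.05
        for _ in range(n_frags):
            length = _sample_length(rng, nucleosomal_fraction)
            u = rng.random()
            if rng.random() < mito_rate:
                chrom = "chrM"
                start = int(rng.integers(0, GENOME["chrM"] - length))
            elif u < p_peak:
                pk = peaks[rng.integers(0, len(peaks))]
                chrom = pk.chrom
                start = int(rng.integers(pk.start - length + 1, pk.end))
                start = max(0, start)
            elif u < p_peak + p_tss:
                tw = tss_windows[rng.integers(0, len(tss_windows))]
                chrom = tw.chrom
                start = int(rng.integers(tw.start - length + 1, tw.end))
                start = max(0, start)
            else:
                chrom = chroms[rng.integers(0, len(chroms))]
                start = int(rng.integers(0, GENOME[chrom] - length))
            dup = 1 + int(rng.poisson(0.3))
            records.append(FragmentRecord(chrom, start, start + length, bc, dup))
    records.sort()

    paths = {
        "fragments": outdir / "fragments.tsv.gz",
        "peaks": outdir / "peaks.bed",
        "tss": outdir / "tss.bed",
        "dhs": outdir / "dhs.bed",
    }
    write_fragments(records, paths["fragments"])
    write_bed(peaks, paths["peaks"])
    write_bed(tss_pt, paths["tss"])
    write_bed(dhs, paths["dhs"])

    st = SimTruth(
        seed=seed,
        params={
            "n_cells": n_cells, "n_noise": n_noise,
            "frags_per_cell": frags_per_cell, "frags_per_noise": frags_per_noise,
            "frip_true": frip_true, "fritss_true": fritss_true,
            "noise_frip": noise_frip,
            "nucleosomal_fraction": nucleosomal_fraction,
            "mito_rate": mito_rate,
        },
        tables={"barcode_class": dict(zip(barcodes, classes)),
                "n_fragments": len(records)},
    )
    st.to_json(outdir / "truth.json")
    return paths, st


def gen_accessibility_matrix(
    n_cells: int = 120,
    n_features: int = 300,
    n_clusters: int = 3,
    depth_range: tuple[int, int] = (100, 400),
    seed: int = 0,
):
    """Binarized accessibility matrix with clusters and a depth gradient.

    Features split into per-cluster blocks; each cell opens a random
    subset of its own cluster's block plus a random genome-wide subset,
    with the subset sizes driven by a per-cell depth drawn uniformly
    from `depth_range` — producing the depth-dominated first LSI
    component seen in real accessibility data.

    Returns (X sparse binary csr, labels, depths).
    """
    from scipy import sparse

    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_clusters), -(-n_cells // n_clusters))[:n_cells]
    depths = rng.integers(*depth_range, size=n_cells)
    block = n_features // n_clusters
    X = np.zeros((n_cells, n_features), dtype=np.int8)
    for i in range(n_cells):
        lo = labels[i] * block
        own = rng.choice(np.arange(lo, lo + block),
                         size=min(depths[i] // 2, block), replace=False)
        anywhere = rng.choice(n_features, size=depths[i] // 2, replace=False)
        X[i, own] = 1
        X[i, anywhere] = 1
    return sparse.csr_matrix(X), labels, X.sum(axis=1)


def gen_trimodal_embeddings(
    n_cells: int = 300,
    groups: list[tuple[int, int]] | None = None,
    dims_per_modality: int = 10,
    noise_sd: float = 1.0,
    separation: float = 5.0,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], SimTruth]:
    """Three row-aligned embeddings, each informative for one cell group.

    `groups` lists (size, informative modality index); sizes must sum
    to `n_cells`. Each group's centroid is displaced from the origin by
    `separation` along a random direction — but only in its informative
    modality; in every other modality the group is isotropic noise of
    scale `noise_sd`. Truth records the group label per cell.
    """
    if groups is None:
        third = n_cells // 3
        groups = [(third, 0), (third, 1), (n_cells - 2 * third, 2)]
    if sum(g[0] for g in groups) != n_cells:
        raise ValueError("group sizes must sum to n_cells")
    rng = np.random.default_rng(seed)
    names = ["rna", "atac", "adt"]
    emb = {m: rng.normal(0.0, noise_sd, size=(n_cells, dims_per_modality))
           for m in names}
    labels = np.empty(n_cells, dtype=int)
    informative = np.empty(n_cells, dtype=int)
    row = 0
    for gi, (size, mod) in enumerate(groups):
        direction = rng.normal(size=dims_per_modality)
        direction *= separation / np.linalg.norm(direction)
        emb[names[mod]][row: row + size] += direction
        labels[row: row + size] = gi
        informative[row: row + size] = mod
        row += size
    st = SimTruth(
        seed=seed,
        params={"n_cells": n_cells, "groups": [list(g) for g in groups],
                "dims_per_modality": dims_per_modality,
                "noise_sd": noise_sd, "separation": separation},
        tables={"labels": labels.tolist(), "informative": informative.tolist(),
                "modalities": names},
    )
    return emb, st
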