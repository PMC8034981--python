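"""Peak-to-feature correlation linkage over aggregated cell groups.

Single-cell accessibility is too sparse for stable Pearson
correlations, so cells are first aggregated into small overlapping
groups of transcriptionally similar cells (seeded anchor cells plus
their nearest embedding neighbors, profiles summed). For every
(peak, feature) pair whose peak lies within a window of the feature's
genomic anchor, the Pearson correlation across groups is computed,
p-values come from the t-distribution transform of r with
n_groups - 2 degrees of freedom, and Benjamini-Hochberg FDR is applied
over all tested pairs. Peak-to-protein links reuse the identical
machinery with the ADT aggregate matrix in place of the RNA matrix.
Overlap between groups induces dependence between aggregate columns;
the FDR is therefore approximate, as in the tool this follows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from trimux.intervals import GenomicInterval, IntervalSet

__all__ = ["PeakFeatureLink", "aggregate_cells", "aggregate_matrix",
           "peak_feature_links"]


@dataclass
class PeakFeatureLink:
    """One retained peak-feature correlation."""

    peak: GenomicInterval
    feature: str
    r: float
    pvalue: float
    fdr: float
    kind: str  # "peak_to_rna" | "peak_to_protein"


def aggregate_cells(
    embedding: np.ndarray,
    n_groups: int = 100,
    group_size: int = 20,
    seed: int = 0,
) -> list[np.ndarray]:
    """Seeded overlapping cell groups: anchor + nearest neighbors.

    `n_groups` anchor cells are drawn without replacement; each group
    is the anchor plus its (group_size - 1) nearest neighbors in the
    embedding. Groups may overlap. Deterministic for fixed seed.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if group_size > n:
        raise ValueError(f"group_size {group_size} > n_cells {n}")
    if n_groups > n:
        raise ValueError(f"n_groups {n_groups} > n_cells {n}")
    rng = np.random.default_rng(seed)
    anchors = rng.choice(n, size=n_groups, replace=False)
    if group_size == 1:
        return [np.array([a]) for a in anchors]
    nn = NearestNeighbors(n_neighbors=group_size, algorithm="brute").fit(embedding)
    _, idx = nn.kneighbors(embedding[anchors])
    groups = []
    for a, row in zip(anchors, idx):
        members = [a] + [j for j in row if j != a][: group_size - 1]
        groups.append(np.asarray(members[:group_size]))
    return groups


def aggregate_matrix(values: np.ndarray, groups: list[np.ndarray]) -> np.ndarray:
    """Sum per-cell profiles within groups: (features, cells) ->
    (features, groups)."""
    values = np.asarray(values)
    return np.column_stack([values[:, g].sum(axis=1) for g in groups])


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and two-sided p via the t transform with n-2 df."""
    n = len(x)
    r = float(np.corrcoef(x, y)[0, 1])
    r_c = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_c * np.sqrt((n - 2) / (1.0 - r_c * r_c))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def peak_feature_links(
    peak_agg: np.ndarray,
    feature_agg: np.ndarray,
    peaks: IntervalSet,
    feature_names: list[str],
    feature_coords: dict[str, tuple[str, int]],
    window_bp: int = 250_000,
    cor_cutoff: float = 0.05,
    fdr_cutoff: float = 0.01,
    kind: str = "peak_to_rna",
) -> list[PeakFeatureLink]:
    """Correlate peak accessibility with feature abundance across groups.

    `peak_agg` (n_peaks x n_groups) and `feature_agg` (n_features x
    n_groups) must be column-aligned by group. Pairs are tested only
    when the peak interval lies within `window_bp` of the feature's
    anchor position (same chromosome; gap distance, zero if the anchor
    falls inside the peak). Zero-variance vectors skip the pair.
    Retained links satisfy |r| >= cor_cutoff and BH FDR <= fdr_cutoff.
    """
    peak_agg = np.asarray(peak_agg, dtype=float)
    feature_agg = np.asarray(feature_agg, dtype=float)
    if peak_agg.shape[1] != feature_agg.shape[1]:
        raise ValueError("peak and feature aggregates have differing group counts")
    if peak_agg.shape[0] != len(peaks):
        raise ValueError("peak matrix rows do not match peak intervals")
    if feature_agg.shape[0] != len(feature_names):
        raise ValueError("feature matrix rows do not match feature names")

    tested: list[tuple[int, str, float, float]] = []
    for fi, feat in enumerate(feature_names):
        if feat not in feature_coords:
            continue
        chrom, anchor = feature_coords[feat]
        lo, hi = anchor - window_bp, anchor + window_bp + 1
        fvec = feature_agg[fi]
        if np.ptp(fvec) == 0:
            continue
        for pi in peaks.overlapping(chrom, max(0, lo), hi):
            pvec = peak_agg[pi]
            if np.ptp(pvec) == 0:
                continue
            r, p = _pearson_with_p(pvec, fvec)
            tested.append((pi, feat, r, p))

    if not tested:
        return []
    pvals = np.array([t[3] for t in tested])
    fdrs = multipletests(pvals, method="fdr_bh")[1]
    links = []
    for (pi, feat, r, p), q in zip(tested, fdrs):
        if abs(r) >= cor_cutoff and q <= fdr_cutoff:
            links.append(PeakFeatureLink(peaks[pi], feat, r, p, float(q), kind))
    return links


def links_table(links: list[PeakFeatureLink]) -> pd.DataFrame:
    """Links as a DataFrame (chrom, start, end, feature, r, fdr, kind)."""
    return pd.DataFrame(
        [
            {
                "chrom": l.peak.chrom,
                "start": l.peak.start,
                "end": l.peak.end,
                "feature": l.feature,
                "r": l.r,
                "fdr": l.fdr,
                "kind": l.kind,
            }
            for l in links
        ]
    )
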