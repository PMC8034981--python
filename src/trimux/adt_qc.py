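"""ADT feature QC against the isotype control, and normalization.

An isotype control (here typically mouse IgG1k) binds no human target,
so its per-cell counts estimate non-specific antibody background. Two
filtering rules are provided: a one-sided Mann-Whitney comparison of
each feature against the control (features indistinguishable from
background are removed), and a per-cell fold-enrichment rule that
removes features with weak enrichment over the control in too many
cells.

Normalization divides each count by thousands of total ADT UMIs for
that cell and applies log10(scaled + 1); the result is invariant to
per-cell sequencing depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AdtFilterReport",
    "filter_features_mw",
    "filter_features_fold",
    "normalize_adt",
    "scale_features",
]


@dataclass
class AdtFilterReport:
    """Decision record for one antibody feature."""

    feature: str
    removed: bool
    rule: str
    pvalue: float | None = None
    flag_fraction: float | None = None


def _mw_greater_p(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (x stochastically greater than y) Mann-Whitney p-value.

    Small tie-free samples use the exact null distribution of U; larger
    or tied samples use the tie-corrected normal approximation. The
    degenerate case with zero rank variance (e.g. both vectors constant
    and equal) returns p = 1 by convention.
    """
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    small = max(len(x), len(y)) <= 50
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if small and tie_free else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def filter_features_mw(
    counts: pd.DataFrame,
    control_feature: str,
    alpha_remove: float = 1e-9,
) -> list[AdtFilterReport]:
    """Remove features whose counts are not clearly above the control.

    For each non-control feature, a one-sided Mann-Whitney test asks
    whether its per-cell counts are stochastically greater than the
    control's across the same cells. Features with p > `alpha_remove`
    are considered background-like and removed. The control itself is
    always removed from the analysis set.
    """
    if control_feature not in counts.columns:
        raise ValueError(f"control feature {control_feature!r} not in matrix")
    control = counts[control_feature].to_numpy(dtype=float)
    reports = [AdtFilterReport(control_feature, removed=True, rule="control")]
    for feat in counts.columns:
        if feat == control_feature:
            continue
        p = _mw_greater_p(counts[feat].to_numpy(dtype=float), control)
        reports.append(
            AdtFilterReport(feat, removed=p > alpha_remove, rule="mann_whitney",
                            pvalue=p)
        )
    return reports


def filter_features_fold(
    counts: pd.DataFrame,
    control_feature: str,
    fold: float = 16.0,
    cell_frac: float = 0.005,
) -> list[AdtFilterReport]:
    """Remove features with weak per-cell enrichment over the control.

    Per cell, ratio = feature count / control count; cells whose
    control count is zero use a pseudocount of 1 in the denominator
    (this only strengthens flagging, a conservative choice). A cell is
    flagged when ratio <= `fold`; a feature is removed when flagged in
    more than `cell_frac` of cells.
    """
    if control_feature not in counts.columns:
        raise ValueError(f"control feature {control_feature!r} not in matrix")
    control = counts[control_feature].to_numpy(dtype=float)
    denom = np.where(control > 0, control, 1.0)
    reports = [AdtFilterReport(control_feature, removed=True, rule="control")]
    for feat in counts.columns:
        if feat == control_feature:
            continue
        ratio = counts[feat].to_numpy(dtype=float) / denom
        frac = float(np.mean(ratio <= fold))
        reports.append(
            AdtFilterReport(feat, removed=frac > cell_frac, rule="fold_flag",
                            flag_fraction=frac)
        )
    return reports


def retained_features(reports: list[AdtFilterReport]) -> list[str]:
    return [r.feature for r in reports if not r.removed]


def normalize_adt(counts: pd.DataFrame) -> pd.DataFrame:
    """Depth-normalize and log-transform ADT counts.

    value(c, f) = log10( count(c, f) / (total(c) / 1000) + 1 ).

    Cells with zero total UMIs are dropped (normalization undefined).
    Zero counts map to exactly 0; the transform is invariant to
    per-cell multiplicative depth and strictly monotone within a cell.
    """
    totals = counts.sum(axis=1)
    kept = counts.loc[totals > 0]
    scaled = kept.div(totals[totals > 0] / 1000.0, axis=0)
    return np.log10(scaled + 1.0)


def scale_features(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-feature z-scaling (mean 0, unit variance) after normalization.

    Matches default ScaleData-style semantics for downstream embedding;
    zero-variance features scale to all zeros.
    """
    mu = normalized.mean(axis=0)
    sd = normalized.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (normalized - mu) / sd
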