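"""Binarized TF-IDF latent semantic indexing (LSI) of accessibility matrices.

Chromatin accessibility matrices are near-binary and extremely sparse;
the standard embedding treats each cell as a "document" over peak or
tile "terms": features detected in more than a minimum fraction of
cells are retained, weighted by term frequency-inverse document
frequency, log-transformed, and decomposed by truncated SVD. The first
component tracks per-cell sequencing depth almost perfectly and is
dropped by default; downstream analyses use components 2..30 (2..20
for the low-depth plate-based preset, with feature fraction 0.005).
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import TruncatedSVD
from sklearn.utils.validation import check_is_fitted

__all__ = ["LsiTransformer", "fit_lsi", "project_lsi"]


class LsiTransformer(BaseEstimator, TransformerMixin):
    """TF-IDF LSI with depth-component removal.

    Parameters
    ----------
    min_cell_frac : float, default 0.03
        Retain features detected in strictly more than this fraction of
        cells (0.005 for the plate-based preset).
    n_dims : int, default 50
        Number of singular dimensions to compute.
    keep : tuple of int, default (2, 30)
        1-based inclusive range of dimensions returned by `transform`;
        the default drops dimension 1 (the depth component). Pass
        ``(1, n_dims)`` to keep everything.
    scale : float, default 1e4
        Weight = log1p(TF * IDF * scale); the scale constant puts
        typical TF*IDF values into a range where the log matters.

    Attributes
    ----------
    feature_index_ : ndarray of int
        Column indices of retained features in the input matrix.
    idf_ : ndarray
        Inverse document frequency (n_cells / feature count) per
        retained feature.
    components_ : ndarray (n_dims, n_retained)
        Right singular vectors.
    singular_values_ : ndarray (n_dims,)
    embedding_ : ndarray (n_cells, len(kept_dims_))
        Training-set scores restricted to kept dimensions.
    scores_ : ndarray (n_cells, n_dims)
        All training-set scores (dimension 1 included), for diagnostics
        such as the depth correlation that motivates dropping it.
    """

    def __init__(self, min_cell_frac: float = 0.03, n_dims: int = 50,
                 keep: tuple[int, int] = (2, 30), scale: float = 1e4):
        self.min_cell_frac = min_cell_frac
        self.n_dims = n_dims
        self.keep = keep
        self.scale = scale

    @classmethod
    def icicle(cls, n_dims: int = 50) -> "LsiTransformer":
        """Preset for plate-based low-depth data: 0.5% feature fraction,
        keep dimensions 2..20."""
        return cls(min_cell_frac=0.005, n_dims=n_dims, keep=(2, 20))

    # ------------------------------------------------------------------

    def _validate(self, X) -> sparse.csr_matrix:
        X = sparse.csr_matrix(X)
        if X.nnz and X.data.max() > 1:
            raise ValueError("input must be binarized (values in {0, 1})")
        return X

    def _weight(self, X: sparse.csr_matrix, idf: np.ndarray) -> sparse.csr_matrix:
        row_sums = np.asarray(X.sum(axis=1)).ravel()
        if np.any(row_sums == 0):
            raise ValueError(
                f"{int((row_sums == 0).sum())} cells have no retained features; "
                "TF undefined"
            )
        tf = sparse.diags(1.0 / row_sums) @ X
        w = tf @ sparse.diags(idf)
        w.data = np.log1p(w.data * self.scale)
        return w

    def fit(self, X, y=None):
        return self._fit(X)[0]

    def _fit(self, X):
        X = self._validate(X)
        n_cells, n_features = X.shape
        if n_cells < self.n_dims:
            raise ValueError(f"need >= {self.n_dims} cells, got {n_cells}")
        cell_counts = np.asarray((X > 0).sum(axis=0)).ravel()
        keep_mask = cell_counts / n_cells > self.min_cell_frac
        n_kept = int(keep_mask.sum())
        if n_kept < self.n_dims:
            raise ValueError(
                f"only {n_kept} features pass min_cell_frac={self.min_cell_frac}; "
                f"need >= n_dims={self.n_dims}"
            )
        self.feature_index_ = np.flatnonzero(keep_mask)
        Xk = X[:, self.feature_index_]
        self.idf_ = n_cells / np.asarray(Xk.sum(axis=0)).ravel()
        w = self._weight(Xk, self.idf_)
        svd = TruncatedSVD(n_components=self.n_dims, algorithm="arpack",
                           random_state=0)
        scores = svd.fit_transform(w)
        self.components_ = svd.components_
        self.singular_values_ = svd.singular_values_
        lo, hi = self.keep
        self.kept_dims_ = np.arange(lo - 1, min(hi, self.n_dims))
        self.scores_ = scores
        self.embedding_ = scores[:, self.kept_dims_]
        return self, self.embedding_

    def fit_transform(self, X, y=None):
        return self._fit(X)[1]

    def transform(self, X):
        """Project new cells through the stored IDF and components.

        Features are aligned by column index with the training matrix;
        unseen (dropped) features are ignored. All-zero cells (no
        retained feature) are rejected — their TF is undefined.
        """
        check_is_fitted(self, "components_")
        X = self._validate(X)
        Xk = X[:, self.feature_index_]
        w = self._weight(Xk, self.idf_)
        return (w @ self.components_.T)[:, self.kept_dims_]


def fit_lsi(X, min_cell_frac: float = 0.03, n_dims: int = 50,
            keep: tuple[int, int] = (2, 30)):
    """Fit LSI on a binarized matrix; returns (model, embedding)."""
    return LsiTransformer(min_cell_frac=min_cell_frac, n_dims=n_dims,
                          keep=keep)._fit(X)


def project_lsi(model: LsiTransformer, X):
    """Project a binarized matrix through a fitted model."""
    return model.transform(X)
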