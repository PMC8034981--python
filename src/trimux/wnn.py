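"""N-modality weighted nearest neighbors (WNN) integration.

Each cell i carries one embedding vector per modality (e.g. RNA PCA,
ATAC LSI, normalized ADT features), row-aligned across modalities. For
every ordered modality pair (alpha, beta) the modality-alpha vector of
cell i is predicted as the mean of the alpha-vectors of i's k nearest
neighbors found in beta's space. Prediction quality is measured by an
exponential affinity kernel

    theta = exp( -max(d - d_near, 0) / (sigma - d_near) )

with per-cell bandwidths: d_near is the distance to the nearest
non-self within-modality neighbor and sigma the distance to the k-th.
The per-cell modality affinity ratio compares the within-modality
prediction against the best cross-modality one,

    S_alpha(i) = theta_alpha(x_i, xhat_i_knn_alpha)
                 / ( max_{beta != alpha} theta_alpha(x_i, xhat_i_knn_beta)
                     + eps ),

weights are the row-wise softmax w_alpha(i) = exp(S_alpha(i)) /
sum_beta exp(S_beta(i)), and the integrated similarity of cells i, j is

    theta_weighted(i, j) = sum_alpha w_alpha(i) * theta_alpha(x_i, x_j),

which is not symmetric (the weights are i's). The integrated kNN graph
keeps each cell's graph_k highest-theta_weighted neighbors.

The kernel family follows the two-modality method this construction
generalizes; S can reach the order of 1/eps, so the softmax is
computed with max subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = ["WeightedNearestNeighbors", "WnnResult", "affinity"]

EPSILON_DEFAULT = 1e-4


def affinity(d: np.ndarray, d_near: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Exponential affinity kernel, elementwise over broadcastable arrays.

    theta = 1 when d <= d_near; strictly decreasing in d beyond d_near.
    Degenerate bandwidths (sigma <= d_near) fall back to a tiny positive
    width so the kernel stays defined.
    """
    width = np.maximum(sigma - d_near, 1e-12)
    return np.exp(-np.maximum(d - d_near, 0.0) / width)


def _softmax_rows(S: np.ndarray) -> np.ndarray:
    # max-subtracted (S can reach ~1/eps); denominator summed in sorted
    # order so the result is exactly invariant to column permutation
    Z = S - S.max(axis=1, keepdims=True)
    e = np.exp(Z)
    denom = np.sort(e, axis=1).sum(axis=1, keepdims=True)
    return e / denom


@dataclass
class WnnResult:
    """Container for WNN outputs (also exposed as fitted attributes)."""

    modalities: list[str]
    S: np.ndarray  # cells x modalities affinity ratios
    W: np.ndarray  # cells x modalities softmax weights
    graph_indices: np.ndarray  # cells x graph_k neighbor indices
    graph_scores: np.ndarray  # cells x graph_k theta_weighted values

    def edge_list(self) -> list[tuple[int, int, float]]:
        return [
            (i, int(j), float(s))
            for i in range(self.graph_indices.shape[0])
            for j, s in zip(self.graph_indices[i], self.graph_scores[i])
        ]


class WeightedNearestNeighbors(BaseEstimator):
    """Sklearn-style estimator for N-modality WNN integration.

    Parameters
    ----------
    k : int, default 20
        Neighbors used for cross-modality prediction and for the
        bandwidth sigma.
    epsilon : float, default 1e-4
        Stabilizer added to the cross-modality denominator of S.
    graph_k : int, default 20
        Neighbors kept per cell in the integrated graph.
    candidate_pool : {"union_of_modality_knn", "all_pairs"}
        Candidate neighbors scored for the final graph: the union of
        each modality's 3*graph_k nearest neighbors, or every other
        cell. The two agree whenever 3*graph_k >= n_cells - 1.

    Attributes (after fit)
    ----------
    modalities_ : list of str
    S_, W_ : ndarray (n_cells, n_modalities)
    graph_indices_, graph_scores_ : ndarray (n_cells, graph_k)
    result_ : WnnResult
    """

    def __init__(self, k: int = 20, epsilon: float = EPSILON_DEFAULT,
                 graph_k: int = 20,
                 candidate_pool: str = "union_of_modality_knn"):
        self.k = k
        self.epsilon = epsilon
        self.graph_k = graph_k
        self.candidate_pool = candidate_pool

    # ------------------------------------------------------------------

    @staticmethod
    def _as_dict(embeddings) -> dict[str, np.ndarray]:
        if isinstance(embeddings, dict):
            return {m: np.asarray(E, dtype=float) for m, E in embeddings.items()}
        return {f"modality_{i}": np.asarray(E, dtype=float)
                for i, E in enumerate(embeddings)}

    def fit(self, embeddings, y=None):
        """Compute S, W and the integrated graph.

        `embeddings`: dict name -> (n_cells, dims) array, or a sequence
        of arrays; rows must be the same cells in the same order.
        """
        emb = self._as_dict(embeddings)
        if len(emb) < 2:
            raise ValueError("need at least 2 modalities")
        names = list(emb)
        n_cells = {E.shape[0] for E in emb.values()}
        if len(n_cells) != 1:
            raise ValueError("modalities have differing cell counts")
        n = n_cells.pop()
        if n <= self.k:
            raise ValueError(f"need more than k={self.k} cells, got {n}")
        m = len(names)

        # all-pairs distances per modality (exact backend)
        D = {a: cdist(emb[a], emb[a]) for a in names}
        # within-modality neighbor order, self excluded
        order = {}
        d_near, sigma = {}, {}
        for a in names:
            Da = D[a].copy()
            np.fill_diagonal(Da, np.inf)
            o = np.argsort(Da, axis=1, kind="stable")
            order[a] = o
            sorted_d = np.take_along_axis(Da, o, axis=1)
            d_near[a] = sorted_d[:, 0]
            sigma[a] = sorted_d[:, self.k - 1]

        # cross-modality predictions: alpha-vectors averaged over the k
        # nearest neighbors found in beta-space
        pred = {}  # (alpha, beta) -> (n, dims_alpha)
        for b in names:
            knn_b = order[b][:, : self.k]
            for a in names:
                pred[(a, b)] = emb[a][knn_b].mean(axis=1)

        # theta_alpha(x_i, xhat_i_knn_beta) with cell i's alpha-bandwidths
        theta_pred = np.empty((n, m, m))  # [i, alpha, beta]
        for ai, a in enumerate(names):
            for bi, b in enumerate(names):
                d = np.linalg.norm(emb[a] - pred[(a, b)], axis=1)
                theta_pred[:, ai, bi] = affinity(d, d_near[a], sigma[a])

        S = np.empty((n, m))
        for ai in range(m):
            within = theta_pred[:, ai, ai]
            cross = np.delete(theta_pred[:, ai, :], ai, axis=1).max(axis=1)
            S[:, ai] = within / (cross + self.epsilon)
        W = _softmax_rows(S)

        # integrated graph over the candidate pool
        graph_k = min(self.graph_k, n - 1)
        idx_out = np.empty((n, graph_k), dtype=int)
        score_out = np.empty((n, graph_k))
        pool_k = min(3 * self.graph_k, n - 1)
        for i in range(n):
            if self.candidate_pool == "all_pairs":
                cand = np.setdiff1d(np.arange(n), [i])
            elif self.candidate_pool == "union_of_modality_knn":
                cand = np.unique(
                    np.concatenate([order[a][i, :pool_k] for a in names])
                )
            else:
                raise ValueError(f"unknown candidate_pool {self.candidate_pool!r}")
            terms = np.stack([
                W[i, ai] * affinity(D[a][i, cand], d_near[a][i], sigma[a][i])
                for ai, a in enumerate(names)
            ])
            # sorted summation: modality order cannot perturb the scores
            theta_w = np.sort(terms, axis=0).sum(axis=0)
            top = np.argsort(-theta_w, kind="stable")[:graph_k]
            idx_out[i] = cand[top]
            score_out[i] = theta_w[top]

        self.modalities_ = names
        self.S_ = S
        self.W_ = W
        self.theta_pred_ = theta_pred
        self.graph_indices_ = idx_out
        self.graph_scores_ = score_out
        self.result_ = WnnResult(names, S, W, idx_out, score_out)
        return self

    def fit_transform(self, embeddings, y=None) -> np.ndarray:
        """Fit and return the per-cell modality weight matrix W."""
        self.fit(embeddings)
        return self.W_

    @property
    def weights_frame(self):
        check_is_fitted(self, "W_")
        import pandas as pd

        return pd.DataFrame(self.W_, columns=self.modalities_)
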