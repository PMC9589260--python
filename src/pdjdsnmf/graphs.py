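"""Feature connectivity graphs and their Laplacians.

A feature graph holds a symmetric nonnegative connectivity matrix ``L``
over the features of one omics, its degree diagonal ``D`` and the graph
Laplacian ``B = D - L``. The trace penalty ``Tr(H B H^T)`` equals the
pairwise quadratic ``1/2 sum_{p,q} L[p,q] ||h_p - h_q||^2``, which is what
makes it a smoothness penalty on factor loadings of connected features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OmicsMatrix, PriorNetwork

__all__ = ["FeatureGraph", "laplacian_from_adjacency", "build_feature_graph"]

_SYM_TOL = 1e-9


@dataclass
class FeatureGraph:
    """Connectivity matrix with derived degree and Laplacian."""

    connectivity: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray

    @property
    def n_features(self) -> int:
        return self.connectivity.shape[0]


def laplacian_from_adjacency(A: np.ndarray) -> FeatureGraph:
    """Build ``B = D - A`` from a symmetric nonnegative adjacency.

    The diagonal of ``A`` is required to be zero and asymmetry beyond 1e-9
    is an error.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(A - A.T).max(initial=0.0) > _SYM_TOL:
        raise ValueError("adjacency must be symmetric")
    if A.size and np.abs(np.diag(A)).max(initial=0.0) > 0:
        raise ValueError("adjacency diagonal must be zero")
    if A.size and A.min(initial=0.0) < 0:
        raise ValueError("adjacency must be nonnegative")
    A = 0.5 * (A + A.T)  # symmetrize away <=1e-9 noise
    D = np.diag(A.sum(axis=1))
    return FeatureGraph(connectivity=A, degree=D, laplacian=D - A)


def build_feature_graph(
    X: OmicsMatrix,
    method: str = "corr_threshold",
    tau: float = 0.8,
    k_neighbors: int = 10,
) -> FeatureGraph:
    """Build a binary connectivity graph from feature-feature correlations.

    ``corr_threshold`` connects features whose absolute Pearson correlation
    is at least ``tau``; ``knn`` connects each feature to its
    ``k_neighbors`` strongest partners by |r|, symmetrized by OR.
    Zero-variance features receive zero connectivity.
    """
    if X.n_samples < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    if method not in ("corr_threshold", "knn"):
        raise ValueError(f"unknown method {method!r}")
    if method == "corr_threshold" and not (0.0 <= tau <= 1.0):
        raise ValueError(f"tau must be in [0, 1], got {tau}")
    if method == "knn" and k_neighbors < 1:
        raise ValueError("k_neighbors must be positive")

    V = X.values
    sd = V.std(axis=0)
    ok = sd > 0
    p = V.shape[1]
    R = np.zeros((p, p))
    if ok.any():
        C = np.corrcoef(V[:, ok], rowvar=False)
        C = np.atleast_2d(C)
        R[np.ix_(ok, ok)] = np.abs(C)
    np.fill_diagonal(R, 0.0)

    if method == "corr_threshold":
        A = (R >= tau).astype(float)
        A[~ok, :] = 0.0
        A[:, ~ok] = 0.0
    else:
        A = np.zeros((p, p))
        k = min(k_neighbors, p - 1)
        for j in range(p):
            if not ok[j]:
                continue
            order = np.argsort(-R[j])[:k]
            A[j, order[R[j, order] > 0]] = 1.0
        A = np.maximum(A, A.T)  # OR-symmetrization
    np.fill_diagonal(A, 0.0)
    return laplacian_from_adjacency(A)


def graph_from_prior(P: PriorNetwork) -> FeatureGraph:
    """Laplacian graph of a binary PPI prior."""
    return laplacian_from_adjacency(P.adjacency)


def write_adjacency(g: FeatureGraph, path, feature_ids=None) -> None:
    """Export the connectivity matrix as TSV for inspection."""
    import pandas as pd

    ids = feature_ids if feature_ids is not None else [str(i) for i in range(g.n_features)]
    pd.DataFrame(g.connectivity, index=ids, columns=ids).to_csv(path, sep="\t")
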