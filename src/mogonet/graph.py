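"""Weighted sample-similarity networks.

Each omics view induces a graph whose nodes are samples and whose edge
weights are cosine similarities, kept when they reach a threshold ``eps``.
``eps`` is set implicitly through ``k``, the average number of retained
edges per node counting self-connections: it is the largest threshold for
which the average count is still at least ``k``.  The retained adjacency is
then renormalized with self-loops,

    A_tilde = D_hat^{-1/2} (A + I) D_hat^{-1/2},

the symmetric scaling that keeps graph-convolution propagation stable
(all eigenvalues of A_tilde lie in [-1, 1]).

New samples are classified transductively: each test sample is appended to
the training graph on its own, only its similarity row/column is computed,
and the extended graph is renormalized.  With ``k = 1`` no off-diagonal
edge survives, A_tilde is the identity, and graph convolution reduces to an
ordinary fully connected layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "cosine_similarity_matrix",
    "cosine_similarity_cross",
    "select_epsilon",
    "build_adjacency",
    "normalize_adjacency",
    "SimilarityGraph",
    "build_graph",
    "extend_for_test",
]


def _unit_rows(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature matrix")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    safe = np.where(norms > 0, norms, 1.0)
    U = X / safe
    U[norms[:, 0] == 0] = 0.0  # zero-norm rows: similarity 0 to everything
    return U


def cosine_similarity_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities; zero-norm rows get similarity 0 everywhere."""
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    U = _unit_rows(X)
    S = U @ U.T
    np.clip(S, -1.0, 1.0, out=S)
    S = (S + S.T) / 2.0
    nonzero = np.linalg.norm(X, axis=1) > 0
    S[np.diag_indices_from(S)] = np.where(nonzero, 1.0, 0.0)
    return S


def cosine_similarity_cross(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Cosine similarities between rows of X and rows of Y (shape |X| x |Y|)."""
    if X.shape[1] != Y.shape[1]:
        raise ValueError("feature dimensions differ")
    S = _unit_rows(X) @ _unit_rows(Y).T
    np.clip(S, -1.0, 1.0, out=S)
    return S


def select_epsilon(S: np.ndarray, k: int) -> float:
    """Largest threshold retaining on average >= k pairs per node.

    The count runs over all ordered pairs of the n x n similarity matrix
    including self-pairs, so eps is the (k*n)-th largest of the n^2 values.
    Ties at eps are all retained, so the realised average may exceed k.
    """
    n = S.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    flat = np.sort(S.ravel())[::-1]
    return float(flat[k * n - 1])


def build_adjacency(S: np.ndarray, eps: float) -> np.ndarray:
    """Threshold similarities into a weighted adjacency with zero diagonal."""
    A = np.where(S >= eps, S, 0.0)
    np.fill_diagonal(A, 0.0)
    return A


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Self-loop renormalization D_hat^{-1/2} (A + I) D_hat^{-1/2}.

    Weights must be nonnegative — the guarantee that keeps every degree
    positive and the spectrum of A_tilde inside [-1, 1].  Inputs scaled to
    [0, 1] always satisfy this because their cosine similarities are >= 0.
    """
    if A.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)  # >= 1 always, so no division by zero
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class SimilarityGraph:
    """Fitted training-graph state for one omics view."""

    S: np.ndarray
    epsilon: float
    A: np.ndarray
    A_tilde: np.ndarray
    k: int


def build_graph(X: np.ndarray, k: int) -> SimilarityGraph:
    """Build the full training similarity graph for a view at density k."""
    S = cosine_similarity_matrix(X)
    eps = select_epsilon(S, k)
    A = build_adjacency(S, eps)
    return SimilarityGraph(S=S, epsilon=eps, A=A, A_tilde=normalize_adjacency(A), k=k)


def extend_for_test(
    X_tr: np.ndarray,
    X_te: np.ndarray,
    eps: float,
    A_tr: np.ndarray | None = None,
    mode: str = "per_sample",
) -> np.ndarray:
    """Extended normalized adjacencies for transductive prediction.

    In the default ``per_sample`` mode each test sample is appended to the
    training graph independently: only its similarity row/column is computed,
    thresholded with the training ``eps``, and the (n_tr+1)-node graph is
    renormalized.  The pre-normalization adjacency among training nodes is
    the training ``A`` unchanged.  Returns an array of shape
    (n_te, n_tr+1, n_tr+1).

    The optional ``batch`` mode appends all test samples at once (no
    test-test edges); shared renormalization then couples training-node
    degrees across test samples, so it is not the default.  It returns a
    single (n_tr+n_te, n_tr+n_te) matrix.
    """
    X_te = np.atleast_2d(X_te)
    if X_tr.shape[1] != X_te.shape[1]:
        raise ValueError("training and test feature dimensions differ")
    if A_tr is None:
        A_tr = build_adjacency(cosine_similarity_matrix(X_tr), eps)
    n_tr = X_tr.shape[0]
    # one row per test sample, computed row by row so the batched result is
    # bitwise identical to independent single-sample calls
    S_cross = np.vstack(
        [cosine_similarity_cross(X_te[t : t + 1], X_tr) for t in range(X_te.shape[0])]
    )
    edges = np.where(S_cross >= eps, S_cross, 0.0)
    if edges.min() < 0 or A_tr.min() < 0:
        raise ValueError("adjacency weights must be nonnegative")

    if mode == "batch":
        n_te = X_te.shape[0]
        A_ext = np.zeros((n_tr + n_te, n_tr + n_te))
        A_ext[:n_tr, :n_tr] = A_tr
        A_ext[n_tr:, :n_tr] = edges
        A_ext[:n_tr, n_tr:] = edges.T
        return normalize_adjacency(A_ext)
    if mode != "per_sample":
        raise ValueError("mode must be 'per_sample' or 'batch'")

    n_te = X_te.shape[0]
    base = A_tr + np.eye(n_tr)
    base_deg = base.sum(axis=1)  # training degrees before the test edge
    out = np.zeros((n_te, n_tr + 1, n_tr + 1))
    # vectorised over test samples; identical to looping normalize_adjacency
    deg_tr = base_deg[None, :] + edges  # n_te x n_tr
    deg_te = edges.sum(axis=1) + 1.0
    inv_tr = 1.0 / np.sqrt(deg_tr)
    inv_te = 1.0 / np.sqrt(deg_te)
    # multiplication order matches normalize_adjacency (row factor, then
    # column factor) so the result is bitwise identical to a per-sample loop
    out[:, :n_tr, :n_tr] = base[None, :, :] * inv_tr[:, :, None] * inv_tr[:, None, :]
    out[:, n_tr, :n_tr] = (edges * inv_te[:, None]) * inv_tr
    out[:, :n_tr, n_tr] = (edges * inv_tr) * inv_te[:, None]
    out[:, n_tr, n_tr] = inv_te * inv_te
    return out
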