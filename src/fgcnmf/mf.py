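"""Sparse log-ratio proximity matrix and randomized-SVD initial embedding.

The proximity matrix encodes, on the support of the adjacency H, the
log-ratio between the random-walk transition probability p_ij = H_ij / D_ii
and a per-node negative-sampling weight N_E,j proportional to the column sum
of p.  Factorizing it with a randomized SVD (random range projection, reduced
QR, small dense SVD) gives the initial d-dimensional node representation

    F0 = Q S Sigma^{1/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .graph import HeteroNetwork

__all__ = [
    "ProximityMatrix",
    "FactorizationResult",
    "EmbeddingMatrix",
    "build_proximity",
    "gaussian_test_matrix",
    "randomized_svd",
    "initial_embedding",
]


@dataclass
class EmbeddingMatrix:
    """Per-node d-dimensional vectors, rows in network node order.

    ``layer_tag`` records which stage produced the matrix: "F0" for the
    matrix-factorization initialization, "F<k>" for a single propagated
    layer, "final" for the layer average fed to the classifier.
    """

    node_ids: list[str]
    vectors: np.ndarray
    layer_tag: str = "F0"

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("embedding must be a 2-D matrix")
        if self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("embedding row count does not match node_ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]


@dataclass
class ProximityMatrix:
    """Sparse log-ratio proximity matrix C with its building blocks.

    ``p`` is the row-stochastic transition matrix (rows of zero-degree nodes
    are zero); ``neg_weight`` the per-node negative-sampling weights N_E,
    normalized to sum to 1 over all nodes.
    """

    C: sp.csr_matrix
    p: sp.csr_matrix
    neg_weight: np.ndarray

    @property
    def n(self) -> int:
        return self.C.shape[0]


@dataclass
class FactorizationResult:
    """Randomized-SVD factors of the proximity matrix.

    Q is the orthonormal range basis from the reduced QR of C U (U the
    Gaussian test matrix), Z = Q^T C the projected matrix, and (S, sigma, V)
    its dense SVD truncated to d components.  F0 = Q S diag(sqrt(sigma)).
    """

    Q: np.ndarray
    R: np.ndarray
    Z: np.ndarray
    S: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    F0: np.ndarray


def build_proximity(
    net: HeteroNetwork,
    neg_exponent: float = 1.0,
    clip_nonnegative: bool = False,
) -> ProximityMatrix:
    """Build the sparse proximity matrix C on the support of H.

    For every edge (i, j): ``C_ij = log p_ij - log N_E,j`` with
    ``p_ij = 1 / D_ii`` and ``N_E,j`` proportional to ``(sum_i p_ij)^alpha``
    (alpha = ``neg_exponent``), normalized so the weights sum to 1.  Entries
    off the support are zero; zero-degree nodes get zero rows.
    """
    H = net.H.tocsr()
    if H.nnz == 0:
        raise ValueError("network has no edges")
    D = net.D
    with np.errstate(divide="ignore"):
        inv_deg = np.where(D > 0, 1.0 / np.where(D > 0, D, 1.0), 0.0)
    p = (sp.diags(inv_deg) @ H).tocsr()

    col_mass = np.asarray(p.sum(axis=0)).ravel()
    weights = np.power(col_mass, neg_exponent, where=col_mass > 0,
                       out=np.zeros_like(col_mass))
    total = weights.sum()
    assert total > 0
    neg_weight = weights / total
    # every node with an incident edge receives positive column mass
    deg_pos = D > 0
    assert np.all(neg_weight[deg_pos] > 0)

    coo = H.tocoo()
    vals = np.log(inv_deg[coo.row]) - np.log(neg_weight[coo.col])
    if clip_nonnegative:
        vals = np.maximum(vals, 0.0)
    C = sp.csr_matrix((vals, (coo.row, coo.col)), shape=H.shape)
    C.eliminate_zeros()
    return ProximityMatrix(C=C, p=p, neg_weight=neg_weight)


def gaussian_test_matrix(size: int, d: int, seed: int) -> np.ndarray:
    """An i.i.d. N(0, 1/d) test matrix of shape (size, d), seed-determined."""
    if d < 1 or d > size:
        raise ValueError(f"need 1 <= d <= size, got d={d}, size={size}")
    rng = np.random.default_rng(seed)
    return rng.normal(0.0, np.sqrt(1.0 / d), size=(size, d))


def randomized_svd(
    C,
    d: int,
    seed: int,
    oversample: int = 0,
    power_iters: int = 0,
) -> FactorizationResult:
    """Randomized SVD of the (sparse) proximity matrix.

    Projects C through a Gaussian test matrix with ``d + oversample``
    columns, orthonormalizes the range by reduced QR (with optional
    re-orthonormalized power iterations for spectral accuracy), applies a
    small dense SVD to Z = Q^T C, and truncates to the leading d components.
    """
    if isinstance(C, ProximityMatrix):
        C = C.C
    C = sp.csr_matrix(C, dtype=float)
    n = C.shape[0]
    if d < 1:
        raise ValueError("d must be >= 1")
    if d > min(C.shape):
        raise ValueError(f"d={d} exceeds matrix size {min(C.shape)}")
    k = min(d + max(oversample, 0), min(C.shape))

    U = gaussian_test_matrix(n, k, seed)
    Y = C @ U
    for _ in range(power_iters):
        Y, _ = np.linalg.qr(Y)
        Y = C @ (C.T @ Y)
    Q, R = np.linalg.qr(Y)
    Z = Q.T @ C.toarray()
    S_full, sigma_full, Vt_full = np.linalg.svd(Z, full_matrices=False)

    rank = int(np.sum(sigma_full > sigma_full[0] * 1e-12)) if sigma_full.size else 0
    if rank < d:
        warnings.warn(
            f"projected matrix has numerical rank {rank} < d={d}; "
            "trailing singular values are zero-padded",
            stacklevel=2,
        )
        sigma_full = np.where(np.arange(sigma_full.size) < rank, sigma_full, 0.0)

    S = S_full[:, :d]
    sigma = sigma_full[:d]
    V = Vt_full[:d].T
    F0 = Q @ S @ np.diag(np.sqrt(sigma))
    return FactorizationResult(Q=Q, R=R, Z=Z, S=S, sigma=sigma, V=V, F0=F0)


def initial_embedding(fact: FactorizationResult, node_ids: list[str]) -> EmbeddingMatrix:
    """Wrap F0 as an EmbeddingMatrix in network node order."""
    return EmbeddingMatrix(node_ids=list(node_ids), vectors=fact.F0, layer_tag="F0")
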