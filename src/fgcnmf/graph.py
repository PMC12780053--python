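"""Heterogeneous microbe-disease network construction.

Builds the sparsified top-n similarity graphs, the block adjacency

    H = [[SM, MD], [MD^T, SD]],

its degree matrix D, and the symmetrically normalized adjacency
D^{-1/2} H D^{-1/2} used by the propagation stage.  Microbes occupy node
indices 0..n_m-1 and diseases n_m..n_m+n_d-1 throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "RawSimilarity",
    "BinaryNeighborGraph",
    "AssociationMatrix",
    "HeteroNetwork",
    "sparsify_topn",
    "assemble_network",
    "density_stats",
    "sparseness_from_counts",
]


@dataclass
class RawSimilarity:
    """A square within-space similarity matrix with entity identifiers.

    Entries are dimensionless similarities, nominally in [0, 1].  The matrix
    must be square and finite with unique ids; values need not be symmetric
    here (the reader symmetrizes on load).
    """

    entity_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("similarity matrix must be square")
        if self.values.shape[0] != n:
            raise ValueError("entity_ids length does not match matrix size")
        if n < 2:
            raise ValueError("similarity matrix needs at least 2 entities")
        if len(set(self.entity_ids)) != n:
            raise ValueError("entity_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("similarity matrix contains non-finite entries")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass
class BinaryNeighborGraph:
    """Symmetric 0/1 graph produced by top-n neighbor sparsification."""

    entity_ids: list[str]
    adjacency: np.ndarray
    n_neighbors: int

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=np.int8)
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("neighbor graph adjacency must be symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError("neighbor graph must have zero diagonal")

    @property
    def n(self) -> int:
        return len(self.entity_ids)


@dataclass
class AssociationMatrix:
    """Binary microbe x disease association matrix MD."""

    microbe_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.microbe_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix must be binary")
        for ids, axis in ((self.microbe_ids, "microbe"), (self.disease_ids, "disease")):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {axis} ids")

    @property
    def n_microbes(self) -> int:
        return len(self.microbe_ids)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_ids)

    @property
    def n_links(self) -> int:
        return int(self.values.sum())


@dataclass
class HeteroNetwork:
    """The assembled heterogeneous network.

    Attributes
    ----------
    node_ids : list of str
        Microbe ids followed by disease ids.
    H : scipy.sparse.csr_matrix
        Symmetric binary block adjacency.
    D : ndarray
        Diagonal of the degree matrix, ``D[i] = sum_j H[i, j]``.
    H_norm : scipy.sparse.csr_matrix
        ``D^{-1/2} H D^{-1/2}`` with the pseudo-inverse convention: rows and
        columns of isolated nodes are all zero.
    """

    node_ids: list[str]
    H: sp.csr_matrix
    D: np.ndarray
    H_norm: sp.csr_matrix
    n_m: int
    n_d: int

    @property
    def n_nodes(self) -> int:
        return self.n_m + self.n_d


def sparsify_topn(S: RawSimilarity, n: int) -> BinaryNeighborGraph:
    """Keep, for every entity, edges to its n most similar other entities.

    For each row the n largest off-diagonal similarities are selected, ties
    broken by ascending entity index; the returned adjacency is the symmetric
    (OR) closure of the per-row selections with a zero diagonal.  ``n`` at or
    above the matrix size selects all off-diagonal entries with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    size = S.n
    if n >= size:
        warnings.warn(
            f"top-n={n} >= matrix size {size}: selecting all neighbors",
            stacklevel=2,
        )
        n = size - 1
    selected = np.zeros((size, size), dtype=np.int8)
    for i in range(size):
        row = S.values[i]
        # stable sort on -value: descending value, ties by ascending index
        order = np.argsort(-row, kind="stable")
        order = order[order != i]
        selected[i, order[:n]] = 1
    adjacency = np.maximum(selected, selected.T)
    np.fill_diagonal(adjacency, 0)
    return BinaryNeighborGraph(list(S.entity_ids), adjacency, n)


def assemble_network(
    SM: BinaryNeighborGraph, SD: BinaryNeighborGraph, MD: AssociationMatrix
) -> HeteroNetwork:
    """Assemble H = [[SM, MD], [MD^T, SD]], degrees and normalized adjacency."""
    n_m, n_d = MD.n_microbes, MD.n_diseases
    if SM.n != n_m:
        raise ValueError(f"microbe graph size {SM.n} != association rows {n_m}")
    if SD.n != n_d:
        raise ValueError(f"disease graph size {SD.n} != association columns {n_d}")
    if SM.entity_ids != MD.microbe_ids or SD.entity_ids != MD.disease_ids:
        raise ValueError("entity id lists are inconsistent across inputs")
    node_ids = list(MD.microbe_ids) + list(MD.disease_ids)
    if len(set(node_ids)) != len(node_ids):
        raise ValueError("duplicate ids across microbe and disease spaces")

    md = MD.values.astype(np.int8)
    H = sp.bmat(
        [[sp.csr_matrix(SM.adjacency), sp.csr_matrix(md)],
         [sp.csr_matrix(md.T), sp.csr_matrix(SD.adjacency)]],
        format="csr",
        dtype=np.float64,
    )
    D = np.asarray(H.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(D > 0, 1.0 / np.sqrt(np.where(D > 0, D, 1.0)), 0.0)
    Dinv = sp.diags(d_inv_sqrt)
    H_norm = (Dinv @ H @ Dinv).tocsr()
    return HeteroNetwork(node_ids, H, D, H_norm, n_m, n_d)


def sparseness_from_counts(n_microbes: int, n_diseases: int, n_links: int) -> float:
    """Density of a bipartite association set, rounded half-even to 4 decimals."""
    if n_microbes <= 0 or n_diseases <= 0:
        raise ValueError("entity counts must be positive")
    return float(np.round(n_links / (n_microbes * n_diseases), 4))


def density_stats(MD: AssociationMatrix) -> dict:
    """Entity/link counts and sparseness of an association matrix."""
    if MD.values.size == 0:
        raise ValueError("empty association matrix")
    return {
        "n_microbes": MD.n_microbes,
        "n_diseases": MD.n_diseases,
        "n_links": MD.n_links,
        "sparseness": sparseness_from_counts(MD.n_microbes, MD.n_diseases, MD.n_links),
    }
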