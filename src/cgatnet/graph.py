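"""k-nearest-neighbour cell graphs and their normalized adjacency.

The cell graph connects each cell to its k nearest neighbours by Euclidean
distance.  The directed relation is symmetrized by union (an edge exists if
either endpoint selected the other), which keeps the adjacency symmetric as
required by the symmetric normalization

    A_tilde = D_hat^{-1/2} (A + I) D_hat^{-1/2}

used as the propagation operator of the graph convolution.  Adjacency
matrices are stored sparse (CSR); a sample can hold thousands of cells and
only ~2kN entries are nonzero.

Determinism: distance ties are broken by ascending cell index, so graph
construction is reproducible bit-for-bit across runs and platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .io import PointPattern

logger = logging.getLogger(__name__)


@dataclass
class CellGraph:
    """k-NN graph of one sample.

    Attributes
    ----------
    n_cells : int
        Number of nodes N.
    k : int
        Neighbour count actually used (after clamping to N-1).
    A : scipy.sparse.csr_matrix
        Binary symmetric adjacency, zero diagonal.
    D_hat : numpy.ndarray
        Degree vector of A + I; entry i is 1 + degree of node i.
    A_tilde : scipy.sparse.csr_matrix
        Symmetrically normalized self-looped adjacency.
    """

    n_cells: int
    k: int
    A: sp.csr_matrix
    D_hat: np.ndarray
    A_tilde: sp.csr_matrix

    def A_hat(self) -> sp.csr_matrix:
        """Self-looped adjacency A + I."""
        return self.A + sp.identity(self.n_cells, format="csr")


def _knn_edges(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Directed k-NN (rows, cols) with index tie-breaking, self excluded."""
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    # stable sort keeps lower index first among equal distances
    order = np.argsort(d2, axis=1, kind="stable")[:, :k]
    rows = np.repeat(np.arange(n), k)
    return rows, order.ravel()


def build_knn_adjacency(pattern: PointPattern, k: int) -> CellGraph:
    """Build the union-symmetrized k-NN graph of a point pattern.

    ``A[i, j] = 1`` iff j is among i's k nearest other cells or vice versa.
    k is clamped to N-1 for small samples; an N=1 pattern yields an empty
    adjacency with a single self-loop in A_hat.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    coords = np.asarray(pattern.coords, dtype=float)
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    n = coords.shape[0]
    k_eff = min(k, n - 1)
    if k_eff == 0:
        A = sp.csr_matrix((1, 1))
    else:
        rows, cols = _knn_edges(coords, k_eff)
        A = sp.coo_matrix(
            (np.ones(rows.size), (rows, cols)), shape=(n, n)
        ).tocsr()
        A = A.maximum(A.T)  # union symmetrization
        A.data[:] = 1.0
    graph = CellGraph(n_cells=n, k=k_eff, A=A, D_hat=None, A_tilde=None)
    normalize_adjacency(graph)
    n_comp = connected_components(graph.A_hat(), directed=False)[0] if n > 1 else 1
    if n_comp > 1:
        logger.info(
            "sample %s: k-NN graph has %d connected components",
            pattern.sample_id, n_comp,
        )
    return graph


def normalize_adjacency(graph: CellGraph) -> sp.csr_matrix:
    """Compute A_tilde = D_hat^{-1/2} (A + I) D_hat^{-1/2}; stored on the graph."""
    A_hat = graph.A + sp.identity(graph.n_cells, format="csr")
    d_hat = np.asarray(A_hat.sum(axis=1)).ravel()
    inv_sqrt = 1.0 / np.sqrt(d_hat)
    A_tilde = sp.diags(inv_sqrt) @ A_hat @ sp.diags(inv_sqrt)
    graph.D_hat = d_hat
    graph.A_tilde = A_tilde.tocsr()
    return graph.A_tilde


def edge_list(graph: CellGraph) -> np.ndarray:
    """Undirected edges as an (E, 2) int array with i < j, for export."""
    coo = sp.triu(graph.A, k=1).tocoo()
    edges = np.stack([coo.row, coo.col], axis=1).astype(np.int64)
    order = np.lexsort((edges[:, 1], edges[:, 0]))
    return edges[order]
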