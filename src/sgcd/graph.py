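"""Cell-type-aware weighted spatial adjacency graphs.

Pipeline: symmetrized K-nearest-neighbor graph on spot coordinates ->
per-edge cell-type similarity of the two spots' compositions (Jensen-
Shannon divergence by default; cosine or Pearson as alternatives) ->
score S = 1 / (1 + divergence) -> edge weight gamma + (1 - gamma) * S, so
spatial neighbors never fall below the baseline weight gamma even when
their cell types differ completely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import rel_entr

from .proportions import ProportionMatrix

__all__ = [
    "WeightedGraph",
    "NormalizedAdjacency",
    "knn_edges",
    "similarity",
    "similarity_to_score",
    "weight_edges",
    "normalize_adjacency",
    "permute_features",
]


@dataclass
class WeightedGraph:
    """Symmetric weighted adjacency: edges stored once with i < j."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int, i < j
    weights: np.ndarray  # (m,)
    gamma: float
    K: int

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.edges):
            raise ValueError("weights length does not match edges")
        if np.any(self.edges[:, 0] >= self.edges[:, 1]):
            raise ValueError("edges must satisfy i < j (no self-edges)")

    def to_sparse(self) -> sp.csr_matrix:
        """Symmetric CSR weighted adjacency (zero diagonal)."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        A = sp.coo_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([i, j]), np.concatenate([j, i])),
            ),
            shape=(self.n_nodes, self.n_nodes),
        )
        return A.tocsr()


@dataclass
class NormalizedAdjacency:
    """Symmetrically normalized adjacency D^(-1/2) (A [+ I]) D^(-1/2)."""

    matrix: sp.csr_matrix
    self_loops: bool


def knn_edges(coords: np.ndarray, K: int = 4) -> sp.csr_matrix:
    """Binary symmetrized KNN adjacency on spatial coordinates.

    Each node is linked to its ``K`` nearest neighbors (ties broken by
    index); the digraph is symmetrized by A = min(A + A^T, 1). Distances
    are computed exactly in row chunks, so results are deterministic.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if K >= n:
        warnings.warn(f"K={K} >= n nodes; lowering to {n - 1}")
        K = n - 1
    if K < 1:
        raise ValueError("K must be at least 1")

    sq_norms = (coords**2).sum(axis=1)
    rows, cols = [], []
    chunk = max(1, int(2**22 // max(n, 1)))
    dup_warned = False
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = (
            sq_norms[start:stop, None] - 2.0 * coords[start:stop] @ coords.T + sq_norms
        )
        rng = np.arange(start, stop)
        d2[np.arange(stop - start), rng] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")  # ties -> lowest index
        nbrs = order[:, :K]
        if not dup_warned and np.any(
            np.take_along_axis(d2, nbrs, axis=1) <= 1e-18
        ):
            warnings.warn("duplicate coordinates found; neighbor ties broken by index")
            dup_warned = True
        rows.append(np.repeat(rng, K))
        cols.append(nbrs.ravel())
    A = sp.coo_matrix(
        (np.ones(n * K), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()
    A = A + A.T
    A.data = np.minimum(A.data, 1.0)
    return A


def _jsd(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Base-2 Jensen-Shannon divergence, rows of p vs rows of q; in [0, 1]."""
    m = 0.5 * (p + q)
    kl_pm = rel_entr(p, m).sum(axis=-1)
    kl_qm = rel_entr(q, m).sum(axis=-1)
    return (0.5 * (kl_pm + kl_qm)) / np.log(2.0)


def similarity(p, q, method: str = "jsd") -> float:
    """Cell-type similarity of two composition vectors.

    ``jsd`` returns the base-2 Jensen-Shannon divergence (0 identical,
    1 disjoint); ``cosine`` and ``pearson`` return the raw similarity in
    [-1, 1].
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if method == "jsd":
        if np.any(p < 0) or np.any(q < 0):
            raise ValueError("jsd requires non-negative inputs")
        if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
            raise ValueError("jsd requires probability vectors summing to 1")
        return float(_jsd(p, q))
    if method == "cosine":
        np_, nq = np.linalg.norm(p), np.linalg.norm(q)
        if np_ == 0 or nq == 0:
            raise ValueError("cosine similarity undefined for a zero vector")
        return float(p @ q / (np_ * nq))
    if method == "pearson":
        if np.std(p) == 0 or np.std(q) == 0:
            raise ValueError("pearson undefined for a constant vector")
        return float(np.corrcoef(p, q)[0, 1])
    raise ValueError(f"unknown similarity method {method!r}")


def similarity_to_score(sim: float) -> float:
    """Map a non-negative divergence to a score S = 1 / (1 + sim) in (0, 1]."""
    if sim < 0:
        raise ValueError(
            "similarity_to_score expects a non-negative divergence; map "
            "cosine/pearson similarities to 1 - sim first"
        )
    return 1.0 / (1.0 + sim)


def _edge_divergence(
    p: np.ndarray, q: np.ndarray, method: str, transform: str
) -> np.ndarray:
    """Vectorized divergence for edge endpoint composition rows."""
    if method == "jsd":
        return _jsd(p, q)
    if method == "cosine":
        num = (p * q).sum(axis=1)
        den = np.linalg.norm(p, axis=1) * np.linalg.norm(q, axis=1)
        if np.any(den == 0):
            raise ValueError("cosine similarity undefined for a zero composition")
        sim = num / den
    elif method == "pearson":
        pc = p - p.mean(axis=1, keepdims=True)
        qc = q - q.mean(axis=1, keepdims=True)
        den = np.linalg.norm(pc, axis=1) * np.linalg.norm(qc, axis=1)
        if np.any(den == 0):
            raise ValueError("pearson undefined for a constant composition")
        sim = (pc * qc).sum(axis=1) / den
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    if transform == "corrected":
        return 1.0 - sim
    # literal: use the raw similarity as the 'Sim' term, clipped at 0
    if np.any(sim < 0):
        warnings.warn("negative similarities clipped to 0 under the literal transform")
    return np.clip(sim, 0.0, None)


def weight_edges(
    A: sp.spmatrix,
    props: ProportionMatrix,
    gamma: float = 0.2,
    method: str = "jsd",
    transform: str = "corrected",
) -> WeightedGraph:
    """Weight the binary adjacency by cell-type similarity.

    Every edge gets w = gamma + (1 - gamma) * S_ij with
    S_ij = 1 / (1 + divergence); weights therefore lie in [gamma, 1].
    ``transform="corrected"`` (default) turns cosine/pearson similarities
    into divergences 1 - sim before applying the score; ``"literal"``
    feeds the raw similarity through the score formula unchanged.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    A = sp.csr_matrix(A)
    n = A.shape[0]
    if props.n_spots != n:
        raise ValueError(
            f"proportions ({props.n_spots} rows) do not align with {n} graph nodes"
        )
    coo = sp.triu(A, k=1).tocoo()
    edges = np.column_stack([coo.row, coo.col])
    div = _edge_divergence(
        props.values[coo.row], props.values[coo.col], method, transform
    )
    scores = 1.0 / (1.0 + div)
    weights = gamma + (1.0 - gamma) * scores
    return WeightedGraph(
        n_nodes=n, edges=edges, weights=weights, gamma=gamma, K=0
    )


def normalize_adjacency(
    G: WeightedGraph | sp.spmatrix, self_loops: bool = True
) -> NormalizedAdjacency:
    """Symmetric normalization D^(-1/2) (A [+ I]) D^(-1/2).

    With ``self_loops=True`` (default) the identity is added before
    normalization so each node keeps its own signal during convolution;
    ``self_loops=False`` applies the literal formula and raises on
    zero-degree nodes.
    """
    A = G.to_sparse() if isinstance(G, WeightedGraph) else sp.csr_matrix(G)
    n = A.shape[0]
    if self_loops:
        A = A + sp.identity(n, format="csr")
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        bad = np.flatnonzero(deg <= 0)
        raise ValueError(
            f"zero-degree node(s) {bad[:10].tolist()}; enable self_loops or "
            "connect them"
        )
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return NormalizedAdjacency(
        matrix=(d_inv_sqrt @ A @ d_inv_sqrt).tocsr(), self_loops=self_loops
    )


def permute_features(X: np.ndarray, rng_seed) -> np.ndarray:
    """Row-permuted copy of the feature matrix (graph topology untouched).

    This is the corruption step of the contrastive objective: spot
    coordinates and edges stay fixed while the spot <-> expression
    correspondence is shuffled. ``rng_seed`` may be an int or a
    :class:`numpy.random.Generator`.
    """
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    X = np.asarray(X)
    return X[rng.permutation(X.shape[0])]
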