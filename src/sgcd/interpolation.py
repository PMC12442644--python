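"""Expression interpolation at gap centroids.

Two modes share the Cauchy kernel k(xi, xj) = 1 / (1 + ||xi - xj||^2 / theta):

* ``kernel`` (default) — normalized-kernel weighting: the value at a new
  location is the convex combination of its neighborhood's expression rows
  with weights alpha_i = k(x_new, x_i) / sum_j k(x_new, x_j).
* ``gp`` — Gaussian-process regression with the same kernel, applied per
  dimension in a PCA latent space and mapped back linearly: posterior mean
  k*^T (K + jitter I)^-1 Z and variance k(x,x) - k*^T (K + jitter I)^-1 k*.

theta sets the spatial dependency strength; the default theta = (modal
nearest-neighbor distance)^2 makes the kernel value between adjacent spots
exactly 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .containers import SpotTable
from .lattice import modal_nn_distance

__all__ = [
    "KernelParams",
    "GPPosterior",
    "cauchy_kernel",
    "interpolation_weights",
    "kernel_interpolate",
    "gp_posterior",
    "fit_theta",
    "interpolate_slide",
]

_JITTER_LADDER = (1e-8, 1e-6, 1e-4)


@dataclass(frozen=True)
class KernelParams:
    """Cauchy-kernel parameters: spatial dependency strength and jitter."""

    theta: float
    jitter: float = 0.0

    def __post_init__(self):
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")


@dataclass
class GPPosterior:
    """GP posterior at one location: per-dimension mean, shared variance."""

    mean: np.ndarray
    variance: float

    def __post_init__(self):
        if self.variance < -1e-9:
            raise ValueError("variance must be non-negative")
        self.variance = max(0.0, float(self.variance))


def _kernel_matrix(a: np.ndarray, b: np.ndarray, theta: float) -> np.ndarray:
    return 1.0 / (1.0 + cdist(a, b, "sqeuclidean") / theta)


def cauchy_kernel(xi, xj, params: KernelParams) -> float:
    """k(xi, xj) = 1 / (1 + ||xi - xj||^2 / theta), in (0, 1]."""
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if not (np.all(np.isfinite(xi)) and np.all(np.isfinite(xj))):
        raise ValueError("coordinates must be finite")
    return float(1.0 / (1.0 + np.sum((xi - xj) ** 2) / params.theta))


def interpolation_weights(x_new, train_coords, params: KernelParams) -> np.ndarray:
    """Normalized kernel weights of ``x_new`` against each training point."""
    train_coords = np.atleast_2d(np.asarray(train_coords, dtype=float))
    if train_coords.shape[0] == 0:
        raise ValueError("empty training set")
    k = _kernel_matrix(
        np.asarray(x_new, dtype=float)[None, :], train_coords, params.theta
    )[0]
    return k / k.sum()


def kernel_interpolate(
    x_new,
    train: SpotTable,
    params: KernelParams,
    neighborhood: int | str = 6,
) -> np.ndarray:
    """Kernel-weighted expression estimate at ``x_new``.

    ``neighborhood`` restricts the weighting to that many nearest spots
    (``"all"`` uses every spot). The result is a convex combination of the
    neighborhood's expression rows.
    """
    x_new = np.asarray(x_new, dtype=float)
    if neighborhood == "all" or neighborhood >= train.n_spots:
        idx = np.arange(train.n_spots)
    else:
        if neighborhood <= 0:
            raise ValueError("neighborhood must be positive")
        tree = cKDTree(train.coords)
        _, idx = tree.query(x_new, k=int(neighborhood))
        idx = np.atleast_1d(idx)
    alpha = interpolation_weights(x_new, train.coords[idx], params)
    return alpha @ train.expr[idx]


def _solve_with_jitter(K: np.ndarray, rhs: np.ndarray, jitter: float):
    """Cholesky solve of (K + jitter I) x = rhs with a jitter ladder."""
    ladder = (jitter,) + tuple(j for j in _JITTER_LADDER if j > jitter)
    n = K.shape[0]
    for j in ladder:
        try:
            c = cho_factor(K + j * np.eye(n), lower=True)
            return cho_solve(c, rhs), j
        except LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "kernel matrix is singular even after the jitter ladder "
        f"{_JITTER_LADDER}; increase jitter or deduplicate coordinates"
    )


def gp_posterior(
    x_new, train_coords, train_values, params: KernelParams
) -> GPPosterior:
    """Zero-mean GP posterior at ``x_new`` under the Cauchy kernel.

    ``train_values`` may be a vector or an (n, d) matrix; the mean is
    computed per column and the predictive variance (shared across
    columns) is floored at 0.
    """
    train_coords = np.atleast_2d(np.asarray(train_coords, dtype=float))
    Z = np.asarray(train_values, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    K = _kernel_matrix(train_coords, train_coords, params.theta)
    k_star = _kernel_matrix(
        np.asarray(x_new, dtype=float)[None, :], train_coords, params.theta
    )[0]
    alpha, _ = _solve_with_jitter(K, np.column_stack([Z, k_star]), params.jitter)
    mean = k_star @ alpha[:, :-1]
    var = 1.0 - float(k_star @ alpha[:, -1])
    if np.asarray(train_values).ndim == 1:
        mean = mean.ravel()
    return GPPosterior(mean=mean, variance=max(0.0, var))


def fit_theta(train: SpotTable, candidate_grid) -> KernelParams:
    """Pick theta by leave-one-out kernel-interpolation squared error.

    For each candidate, every spot is predicted from all the others with
    normalized kernel weights; the theta with the smallest total squared
    error wins (ties go to the smallest theta).
    """
    grid = np.sort(np.asarray(candidate_grid, dtype=float))
    if grid.size == 0:
        raise ValueError("candidate grid is empty")
    if np.any(grid <= 0):
        raise ValueError("theta candidates must be positive")
    if train.n_spots < 10:
        raise ValueError("fit_theta needs at least 10 spots")
    sq = cdist(train.coords, train.coords, "sqeuclidean")
    errors = np.empty(grid.size)
    for t, theta in enumerate(grid):
        W = 1.0 / (1.0 + sq / theta)
        np.fill_diagonal(W, 0.0)
        W /= W.sum(axis=1, keepdims=True)
        errors[t] = float(((W @ train.expr - train.expr) ** 2).sum())
    best = int(np.argmin(errors))  # first minimum = smallest theta on ties
    return KernelParams(theta=float(grid[best]))


def interpolate_slide(
    train: SpotTable,
    gaps,
    params: KernelParams | None = None,
    mode: str = "kernel",
    neighborhood: int = 6,
    latent_dim: int = 20,
) -> SpotTable:
    """Append interpolated pseudo-spots at gap centroids to ``train``.

    Original rows are passed through unchanged; new rows carry
    ``is_interpolated=True``, ids ``gap_<i>`` and (if the input is
    annotated) an empty annotation. ``mode="gp"`` runs GP regression per
    dimension in a ``latent_dim``-component PCA space and maps the
    posterior means back linearly; ``mode="kernel"`` weights expression
    rows directly.
    """
    if mode not in ("kernel", "gp"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    if len(gaps) == 0:
        return train.copy()
    if params is None:
        params = KernelParams(theta=modal_nn_distance(train.coords) ** 2)

    centroids = np.array([g.centroid for g in gaps], dtype=float)
    lo, hi = train.coords.min(axis=0), train.coords.max(axis=0)
    if np.any(centroids < lo - 1e-9) or np.any(centroids > hi + 1e-9):
        warnings.warn(
            "some gap centroids fall outside the spot bounding box; "
            "check that gaps and spots share a coordinate frame"
        )

    tree = cKDTree(train.coords)
    k = min(int(neighborhood), train.n_spots)
    _, nbr = tree.query(centroids, k=k)
    nbr = np.atleast_2d(nbr)

    if mode == "kernel":
        new_expr = np.empty((len(gaps), train.n_genes))
        for i in range(len(gaps)):
            idx = nbr[i]
            alpha = interpolation_weights(centroids[i], train.coords[idx], params)
            new_expr[i] = alpha @ train.expr[idx]
    else:
        from sklearn.decomposition import PCA

        d = min(latent_dim, train.n_spots, train.n_genes)
        pca = PCA(n_components=d, svd_solver="full", random_state=0)
        latent = pca.fit_transform(train.expr)
        new_latent = np.empty((len(gaps), d))
        for i in range(len(gaps)):
            idx = nbr[i]
            post = gp_posterior(centroids[i], train.coords[idx], latent[idx], params)
            new_latent[i] = post.mean
        new_expr = pca.inverse_transform(new_latent)

    gap_ids = np.array([f"gap_{i}" for i in range(len(gaps))])
    annotation = None
    if train.annotation is not None:
        annotation = np.concatenate([train.annotation, np.full(len(gaps), "")])
    return SpotTable(
        expr=np.vstack([train.expr, new_expr]),
        spot_ids=np.concatenate([train.spot_ids, gap_ids]),
        gene_ids=train.gene_ids.copy(),
        coords=np.vstack([train.coords, centroids]),
        is_interpolated=np.concatenate(
            [train.is_interpolated, np.ones(len(gaps), dtype=bool)]
        ),
        annotation=annotation,
    )
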