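"""From embeddings to spatial-domain labels.

Default route: PCA to 20 dimensions, then a Gaussian mixture with one
shared full covariance across components (the 'EEE' parameterization of
model-based clustering) when the number of domains is known. The
alternative is community detection (Leiden/Louvain) on a 50-nearest-
neighbor graph with an adaptive resolution search over 0.10..3.00 in
steps of 0.01 targeting a given cluster count. An optional spatial
refinement pass reassigns each spot to the modal label within a radius.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "ClusterLabels",
    "pca_reduce",
    "gmm_eee",
    "resolution_search",
    "refine",
]


@dataclass
class ClusterLabels:
    """Cluster assignment per spot plus provenance of how it was produced."""

    labels: np.ndarray
    method: str
    seed: Optional[int] = None
    resolution: Optional[float] = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def pca_reduce(Z: np.ndarray, d: int = 20) -> np.ndarray:
    """Top-d principal components with a deterministic sign convention.

    Each component is flipped so that its largest-magnitude loading is
    positive, making the output independent of the SVD implementation's
    sign choices.
    """
    from sklearn.decomposition import PCA

    Z = np.asarray(Z, dtype=float)
    if d > min(Z.shape):
        raise ValueError(f"d={d} exceeds min(n_samples, n_features)={min(Z.shape)}")
    pca = PCA(n_components=d, svd_solver="full", random_state=0)
    scores = pca.fit_transform(Z)
    comp = pca.components_
    flip = np.sign(comp[np.arange(d), np.argmax(np.abs(comp), axis=1)])
    flip[flip == 0] = 1.0
    return scores * flip


def gmm_eee(Z: np.ndarray, k: int, seed: int = 0, max_iter: int = 300,
            n_init: int = 5) -> ClusterLabels:
    """Gaussian mixture with a single shared full covariance (EEE model).

    All components share one covariance matrix (equal volume, shape and
    orientation); EM is initialized from k-means and the best of
    ``n_init`` starts is kept. Deterministic given ``seed``.
    """
    from sklearn.mixture import GaussianMixture

    Z = np.asarray(Z, dtype=float)
    if k < 2:
        raise ValueError("k must be at least 2")
    if Z.shape[0] <= k:
        raise ValueError("need more samples than clusters")
    gm = GaussianMixture(
        n_components=k,
        covariance_type="tied",
        init_params="kmeans",
        n_init=n_init,
        max_iter=max_iter,
        random_state=seed,
        reg_covar=1e-6,
    )
    labels = gm.fit_predict(Z)
    if not gm.converged_:
        warnings.warn("EM did not converge within max_iter; using best-so-far fit")
    return ClusterLabels(labels=labels, method="gmm_eee", seed=seed)


def _knn_igraph(Z: np.ndarray, n_neighbors: int):
    import igraph as ig

    n = Z.shape[0]
    if n <= n_neighbors:
        warnings.warn(
            f"only {n} points; lowering neighbor count to {n - 1}"
        )
        n_neighbors = n - 1
    tree = cKDTree(Z)
    _, idx = tree.query(Z, k=n_neighbors + 1)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = ig.Graph(n=n, edges=sorted(edges))
    return g


def resolution_search(Z: np.ndarray, k_target: int, algo: str = "leiden",
                      seed: int = 0, n_neighbors: int = 50) -> ClusterLabels:
    """Community detection at the resolution that yields ``k_target`` clusters.

    Builds an (unweighted, symmetrized) ``n_neighbors``-NN graph on the
    embedding, scans resolutions 0.10, 0.11, ..., 3.00 in order and returns
    the first one producing exactly ``k_target`` communities; if none does,
    the resolution minimizing |clusters - k_target| wins (ties -> lowest
    resolution).
    """
    if algo not in ("leiden", "louvain"):
        raise ValueError(f"unknown community detection algorithm {algo!r}")
    Z = np.asarray(Z, dtype=float)
    g = _knn_igraph(Z, n_neighbors)
    resolutions = np.round(np.arange(0.10, 3.0001, 0.01), 2)

    def run(res: float):
        if algo == "leiden":
            import leidenalg

            part = leidenalg.find_partition(
                g,
                leidenalg.RBConfigurationVertexPartition,
                resolution_parameter=float(res),
                seed=seed,
                n_iterations=2,
            )
        else:
            import igraph as ig
            import random as _random

            ig.set_random_number_generator(_random.Random(seed))
            part = g.community_multilevel(resolution=float(res))
        return np.asarray(part.membership, dtype=int)

    best = None  # (|diff|, resolution, labels)
    for res in resolutions:
        labels = run(res)
        k = len(np.unique(labels))
        if k == k_target:
            return ClusterLabels(labels=labels, method=algo, seed=seed,
                                 resolution=float(res))
        diff = abs(k - k_target)
        if best is None or diff < best[0]:
            best = (diff, float(res), labels)
    return ClusterLabels(labels=best[2], method=algo, seed=seed, resolution=best[1])


def refine(labels: ClusterLabels | np.ndarray, coords: np.ndarray,
           radius: float = 50.0) -> ClusterLabels:
    """One synchronous majority-vote pass over spatial neighborhoods.

    Each spot's new label is the modal label among spots within Euclidean
    distance ``radius`` (itself included), computed from the pre-pass
    labels. Ties or a unique modal label equal to the current one keep the
    current label. The radius is in the coordinate units of the input.
    """
    if isinstance(labels, ClusterLabels):
        lab = labels.labels
        method = labels.method + "+refine"
        seed, resolution = labels.seed, labels.resolution
    else:
        lab = np.asarray(labels, dtype=int)
        method, seed, resolution = "refine", None, None
    coords = np.asarray(coords, dtype=float)
    if len(lab) != coords.shape[0]:
        raise ValueError("labels and coords must align")
    if radius < 0:
        raise ValueError("radius must be non-negative")

    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r=radius)
    new = lab.copy()
    for i, nbrs in enumerate(neighborhoods):
        votes = np.bincount(lab[nbrs])
        top = votes.max()
        winners = np.flatnonzero(votes == top)
        if len(winners) == 1:
            new[i] = winners[0]
        # tie -> keep current label
    return ClusterLabels(labels=new, method=method, seed=seed, resolution=resolution)
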