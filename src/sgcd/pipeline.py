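"""End-to-end orchestration: preprocess -> interpolate -> compositions ->
weighted graph -> representation learning -> clustering -> evaluation.

Interpolated pseudo-spots participate in every stage (graph nodes, model
training, clustering) but are dropped from the reported labels and from
any evaluation against ground-truth annotations, which only exist for
measured spots.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from . import __version__
from .clustering import ClusterLabels, gmm_eee, pca_reduce, refine, resolution_search
from .containers import ReferenceSet, SpotTable
from .graph import WeightedGraph, knn_edges, weight_edges
from .interpolation import KernelParams, interpolate_slide, interpolation_weights
from .lattice import modal_nn_distance, partition_gaps
from .metrics import ari, nmi
from .model import EmbeddingResult, ModelConfig, train
from .preprocess import harmonize_genes, preprocess, preprocess_reference
from .proportions import ProportionMatrix, nnls_deconvolve, signature_matrix

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "version_stamp",
           "perturb_proportions"]


@dataclass
class RunConfig:
    """Every stage parameter of one pipeline run."""

    n_clusters: Optional[int] = None
    n_hvg: int = 3000
    K: int = 4
    gamma: float = 0.2
    lambda1: float = 10.0
    lambda2: float = 1.0
    latent_dim: int = 64
    epochs: int = 600
    learning_rate: float = 1e-3
    d_pca: int = 20
    similarity: str = "jsd"
    interp_mode: str = "kernel"
    neighborhood: int = 6
    cluster_method: str = "gmm"  # gmm | leiden | louvain
    refine_labels: bool = False
    refine_radius: float = 50.0
    proportion_noise: float = 0.0
    seed: int = 0
    # ablation switches
    no_recon: bool = False
    no_contrastive: bool = False
    no_weighting: bool = False
    no_interpolation: bool = False


@dataclass
class PipelineResult:
    """Labels for the measured spots plus every intermediate of interest."""

    labels: ClusterLabels
    spot_ids: np.ndarray
    embeddings: np.ndarray
    table: SpotTable  # preprocessed (+ interpolated) table used by the model
    graph: WeightedGraph
    model: EmbeddingResult
    proportions: Optional[ProportionMatrix]
    metrics: dict
    config: RunConfig
    provenance: dict = field(default_factory=dict)


def version_stamp(config: RunConfig) -> dict:
    """Provenance record: package version, config hash and seed."""
    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return {
        "package": "sgcd",
        "version": __version__,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": config.seed,
    }


def perturb_proportions(props: ProportionMatrix, magnitude: float,
                        seed: int = 0) -> ProportionMatrix:
    """Multiply entries by (1 + magnitude * U(-1, 1)) and renormalize rows.

    Models relative uncertainty in external deconvolution results; a
    magnitude of 0.2 corresponds to 20% uniform noise.
    """
    if magnitude < 0:
        raise ValueError("noise magnitude must be non-negative")
    rng = np.random.default_rng(seed)
    noisy = props.values * (1.0 + magnitude * rng.uniform(-1, 1, props.values.shape))
    noisy = np.clip(noisy, 0.0, None)
    sums = noisy.sum(axis=1, keepdims=True)
    uniform = np.full(props.values.shape[1], 1.0 / props.values.shape[1])
    noisy = np.where(sums > 0, noisy / np.where(sums > 0, sums, 1.0), uniform)
    noisy /= noisy.sum(axis=1, keepdims=True)
    return ProportionMatrix(values=noisy, spot_ids=props.spot_ids.copy(),
                            type_names=props.type_names.copy())


def _extend_proportions(props: ProportionMatrix, full: SpotTable,
                        neighborhood: int) -> ProportionMatrix:
    """Give interpolated pseudo-spots kernel-averaged neighbor compositions."""
    from scipy.spatial import cKDTree

    orig = ~full.is_interpolated
    orig_idx = np.flatnonzero(orig)
    if not np.array_equal(props.spot_ids, full.spot_ids[orig_idx]):
        raise ValueError("proportions do not align with the original spots")
    n_new = int(full.is_interpolated.sum())
    if n_new == 0:
        return props
    theta = modal_nn_distance(full.coords[orig_idx]) ** 2
    params = KernelParams(theta=theta)
    tree = cKDTree(full.coords[orig_idx])
    k = min(neighborhood, len(orig_idx))
    new_idx = np.flatnonzero(full.is_interpolated)
    values = np.empty((full.n_spots, props.values.shape[1]))
    values[orig_idx] = props.values
    for i in new_idx:
        _, nbr = tree.query(full.coords[i], k=k)
        nbr = np.atleast_1d(nbr)
        alpha = interpolation_weights(full.coords[i], full.coords[orig_idx][nbr],
                                      params)
        values[i] = alpha @ props.values[nbr]
    values /= values.sum(axis=1, keepdims=True)
    return ProportionMatrix(values=values, spot_ids=full.spot_ids.copy(),
                            type_names=props.type_names.copy())


def _compositions(full: SpotTable, config: RunConfig,
                  reference: Optional[ReferenceSet],
                  proportions: Optional[ProportionMatrix]):
    if proportions is not None:
        return _extend_proportions(proportions, full, config.neighborhood)
    if reference is not None:
        ref = preprocess_reference(reference, config.n_hvg)
        sub_table, sub_ref = harmonize_genes(full, ref)
        sig = signature_matrix(sub_ref)
        return nnls_deconvolve(sub_table, sig)
    return None


def run_pipeline(table: SpotTable, config: RunConfig,
                 reference: Optional[ReferenceSet] = None,
                 proportions: Optional[ProportionMatrix] = None
                 ) -> PipelineResult:
    """Run the full spatial-domain identification pipeline.

    ``proportions`` (covering the measured spots) takes precedence over
    ``reference`` (used for the built-in NNLS deconvolution); with neither,
    the graph falls back to binary weights. Ablation switches on the config
    disable exactly one component each: reconstruction loss, contrastive
    loss, edge weighting, or gap interpolation.
    """
    if config.n_clusters is None:
        raise ValueError("config.n_clusters must be set")

    pre = preprocess(table, config.n_hvg)

    if config.no_interpolation:
        full = pre.copy()
    else:
        gaps = partition_gaps(pre.coords)
        full = interpolate_slide(pre, gaps, mode=config.interp_mode,
                                 neighborhood=config.neighborhood)

    props = None
    if not config.no_weighting:
        props = _compositions(full, config, reference, proportions)
        if props is None:
            warnings.warn("no proportions or reference supplied; "
                          "using a binary (unweighted) graph")
        elif config.proportion_noise > 0:
            props = perturb_proportions(props, config.proportion_noise,
                                        seed=config.seed)

    A = knn_edges(full.coords, K=config.K)
    if props is not None:
        G = weight_edges(A, props, gamma=config.gamma, method=config.similarity)
        G.K = config.K
    else:
        import scipy.sparse as sp

        coo = sp.triu(A, k=1).tocoo()
        G = WeightedGraph(n_nodes=A.shape[0],
                          edges=np.column_stack([coo.row, coo.col]),
                          weights=np.ones(coo.nnz), gamma=1.0, K=config.K)

    model_cfg = ModelConfig(
        latent_dim=config.latent_dim,
        lambda1=0.0 if config.no_recon else config.lambda1,
        lambda2=0.0 if config.no_contrastive else config.lambda2,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        seed=config.seed,
    )
    result = train(full.expr, G, model_cfg)

    Z = result.Z
    if config.cluster_method == "gmm":
        d = min(config.d_pca, Z.shape[0], Z.shape[1])
        reduced = pca_reduce(Z, d=d)
        all_labels = gmm_eee(reduced, k=config.n_clusters, seed=config.seed)
    elif config.cluster_method in ("leiden", "louvain"):
        all_labels = resolution_search(Z, k_target=config.n_clusters,
                                       algo=config.cluster_method,
                                       seed=config.seed)
    else:
        raise ValueError(f"unknown cluster method {config.cluster_method!r}")

    orig = ~full.is_interpolated
    labels = ClusterLabels(labels=all_labels.labels[orig],
                           method=all_labels.method, seed=all_labels.seed,
                           resolution=all_labels.resolution)
    if config.refine_labels:
        labels = refine(labels, full.coords[orig], radius=config.refine_radius)

    metrics: dict = {}
    if table.annotation is not None:
        truth = table.annotation
        known = truth != ""
        if known.sum() >= 2:
            metrics = {
                "ari": ari(labels.labels[known], truth[known]),
                "nmi": nmi(labels.labels[known], truth[known]),
            }

    return PipelineResult(
        labels=labels,
        spot_ids=full.spot_ids[orig],
        embeddings=Z,
        table=full,
        graph=G,
        model=result,
        proportions=props,
        metrics=metrics,
        config=config,
        provenance=version_stamp(config),
    )
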