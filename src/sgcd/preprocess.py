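"""Expression preprocessing.

Pipeline order: library-size normalization (to the median library size of
the slide) -> log1p -> selection of the top highly variable genes by
variance of the log-normalized values -> per-gene scaling to zero mean and
unit variance. Zero-variance genes are dropped before scaling. The same
routine is applied to spot tables and to single-cell references so both
live in a comparable expression space.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np

from .containers import ReferenceSet, SpotTable

__all__ = ["preprocess", "preprocess_reference", "harmonize_genes"]


def _normalize_log(expr: np.ndarray, row_names: np.ndarray) -> np.ndarray:
    if np.any(expr < 0):
        raise ValueError("preprocess expects non-negative input values")
    lib = expr.sum(axis=1)
    if np.any(lib == 0):
        bad = row_names[lib == 0]
        raise ValueError(f"all-zero rows (library size 0): {', '.join(bad[:10])}")
    target = float(np.median(lib))
    return np.log1p(expr * (target / lib)[:, None])


def _select_hvg(logged: np.ndarray, n_hvg: int) -> np.ndarray:
    """Indices of the ``n_hvg`` most variable genes, in original gene order."""
    n_genes = logged.shape[1]
    if n_genes <= n_hvg:
        return np.arange(n_genes)
    var = logged.var(axis=0, ddof=1)
    # stable top-k: sort by (-variance, index)
    order = np.lexsort((np.arange(n_genes), -var))
    return np.sort(order[:n_hvg])


def _scale(logged: np.ndarray):
    """Zero-mean unit-variance per gene; returns (scaled, kept gene mask)."""
    var = logged.var(axis=0, ddof=1)
    keep = var > 1e-12
    centered = logged[:, keep] - logged[:, keep].mean(axis=0)
    return centered / np.sqrt(var[keep]), keep


def _preprocess_matrix(expr: np.ndarray, row_names: np.ndarray, n_hvg: int):
    logged = _normalize_log(expr, row_names)
    if logged.shape[1] < n_hvg:
        warnings.warn(
            f"only {logged.shape[1]} genes present (< n_hvg={n_hvg}); keeping all"
        )
    hvg_idx = _select_hvg(logged, n_hvg)
    scaled, keep = _scale(logged[:, hvg_idx])
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene(s)")
    return scaled, hvg_idx[keep]


def preprocess(table: SpotTable, n_hvg: int = 3000) -> SpotTable:
    """Return a new :class:`SpotTable` with preprocessed expression.

    Retains ``min(n_hvg, n_genes)`` genes (minus any that end up with zero
    variance). The input table is not modified.
    """
    if n_hvg <= 0:
        raise ValueError("n_hvg must be positive")
    scaled, gene_idx = _preprocess_matrix(table.expr, table.spot_ids, n_hvg)
    return replace(table, expr=scaled, gene_ids=table.gene_ids[gene_idx])


def preprocess_reference(ref: ReferenceSet, n_hvg: int = 3000) -> ReferenceSet:
    """Apply the same normalize/log/HVG/scale pipeline to an scRNA reference."""
    cell_names = np.array([f"cell{i}" for i in range(ref.n_cells)])
    scaled, gene_idx = _preprocess_matrix(ref.expr, cell_names, n_hvg)
    return ReferenceSet(
        expr=scaled, gene_ids=ref.gene_ids[gene_idx], cell_type=ref.cell_type
    )


def harmonize_genes(table: SpotTable, ref: ReferenceSet):
    """Restrict both inputs to their shared genes, in a common order.

    The shared genes keep the order they have in ``table``. Raises if the
    intersection is empty.
    """
    shared = [g for g in table.gene_ids if g in set(ref.gene_ids)]
    if not shared:
        raise ValueError("no genes shared between spot table and reference")
    t_pos = {g: i for i, g in enumerate(table.gene_ids)}
    r_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    t_idx = np.array([t_pos[g] for g in shared])
    r_idx = np.array([r_pos[g] for g in shared])
    new_table = table.subset_genes(t_idx)
    new_ref = ReferenceSet(
        expr=ref.expr[:, r_idx], gene_ids=ref.gene_ids[r_idx], cell_type=ref.cell_type
    )
    return new_table, new_ref
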