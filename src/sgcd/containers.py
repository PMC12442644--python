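"""Core in-memory containers shared by every pipeline stage.

A :class:`SpotTable` is the universal carrier: a dense spot x gene
expression matrix with 2-D spot coordinates (platform units, x right,
y down), stable string identifiers, a per-spot flag marking interpolated
pseudo-spots, and an optional ground-truth domain annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["SpotTable", "ReferenceSet"]


def _as_str_array(values) -> np.ndarray:
    return np.asarray(values, dtype=str)


@dataclass
class SpotTable:
    """Spot x gene expression with spatial coordinates.

    Parameters
    ----------
    expr
        ``(n_spots, n_genes)`` non-negative counts or preprocessed values.
    spot_ids, gene_ids
        Unique string identifiers for rows and columns.
    coords
        ``(n_spots, 2)`` spatial coordinates in the source platform's units.
    is_interpolated
        Per-spot flag; ``True`` marks pseudo-spots created by gap
        interpolation. Defaults to all ``False``.
    annotation
        Optional ground-truth domain label per spot (empty string where
        unknown, e.g. for interpolated pseudo-spots).
    """

    expr: np.ndarray
    spot_ids: np.ndarray
    gene_ids: np.ndarray
    coords: np.ndarray
    is_interpolated: np.ndarray = None  # type: ignore[assignment]
    annotation: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.spot_ids = _as_str_array(self.spot_ids)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.is_interpolated is None:
            self.is_interpolated = np.zeros(self.expr.shape[0], dtype=bool)
        else:
            self.is_interpolated = np.asarray(self.is_interpolated, dtype=bool)
        if self.annotation is not None:
            self.annotation = _as_str_array(self.annotation)
        self.validate()

    def validate(self) -> None:
        n, g = self.expr.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match {n} spots"
            )
        if len(self.spot_ids) != n:
            raise ValueError("spot_ids length does not match expression rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match expression columns")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if len(np.unique(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if len(self.is_interpolated) != n:
            raise ValueError("is_interpolated length does not match spots")
        if self.annotation is not None and len(self.annotation) != n:
            raise ValueError("annotation length does not match spots")

    @property
    def n_spots(self) -> int:
        return self.expr.shape[0]

    @property
    def n_genes(self) -> int:
        return self.expr.shape[1]

    def copy(self) -> "SpotTable":
        return SpotTable(
            expr=self.expr.copy(),
            spot_ids=self.spot_ids.copy(),
            gene_ids=self.gene_ids.copy(),
            coords=self.coords.copy(),
            is_interpolated=self.is_interpolated.copy(),
            annotation=None if self.annotation is None else self.annotation.copy(),
        )

    def subset_genes(self, gene_index: np.ndarray) -> "SpotTable":
        return replace(
            self,
            expr=self.expr[:, gene_index],
            gene_ids=self.gene_ids[gene_index],
        )

    def to_anndata(self):
        """Convert to :class:`anndata.AnnData` (coords in ``obsm['spatial']``)."""
        import anndata as ad
        import pandas as pd

        obs = pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id"))
        obs["is_interpolated"] = self.is_interpolated
        if self.annotation is not None:
            obs["annotation"] = self.annotation
        adata = ad.AnnData(
            X=self.expr.copy(),
            obs=obs,
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        return adata

    @classmethod
    def from_anndata(cls, adata) -> "SpotTable":
        import scipy.sparse as sp

        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        coords = None
        for key in ("spatial", "X_spatial"):
            if key in adata.obsm:
                coords = np.asarray(adata.obsm[key], dtype=float)[:, :2]
                break
        if coords is None:
            raise ValueError(
                "missing spatial coordinates: expected obsm['spatial']"
            )
        interp = (
            np.asarray(adata.obs["is_interpolated"], dtype=bool)
            if "is_interpolated" in adata.obs
            else None
        )
        annot = (
            np.asarray(adata.obs["annotation"], dtype=str)
            if "annotation" in adata.obs
            else None
        )
        return cls(
            expr=np.asarray(X, dtype=float),
            spot_ids=np.asarray(adata.obs_names, dtype=str),
            gene_ids=np.asarray(adata.var_names, dtype=str),
            coords=coords,
            is_interpolated=interp,
            annotation=annot,
        )


@dataclass
class ReferenceSet:
    """Single-cell reference: cells x genes expression with cell-type labels."""

    expr: np.ndarray
    gene_ids: np.ndarray
    cell_type: np.ndarray

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_type = _as_str_array(self.cell_type)
        if self.expr.shape[0] != len(self.cell_type):
            raise ValueError("cell_type length does not match cells")
        if self.expr.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match genes")
        if len(np.unique(self.cell_type)) < 2:
            raise ValueError("reference must contain at least 2 cell types")

    @property
    def n_cells(self) -> int:
        return self.expr.shape[0]

    @property
    def types(self) -> np.ndarray:
        return np.unique(self.cell_type)
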