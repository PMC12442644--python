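"""Readers and writers for standard spot-based spatial transcriptomics formats.

Supported formats:

* ``h5ad`` — AnnData with coordinates in ``obsm['spatial']``;
* ``mtx`` — a 10X-style directory with ``matrix.mtx`` (features x barcodes),
  ``barcodes.tsv``, ``features.tsv`` and a ``tissue_positions`` CSV
  (columns barcode, in_tissue, array_row, array_col, pxl_row, pxl_col);
* ``csv`` — a flat table (spot_id, x, y, one column per gene) for fixtures.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .containers import SpotTable

__all__ = ["read_spot_table", "write_spot_table", "read_reference"]

_POSITION_COLUMNS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def _infer_format(path: str) -> str:
    if os.path.isdir(path):
        return "mtx"
    if path.endswith(".h5ad"):
        return "h5ad"
    if path.endswith((".csv", ".tsv")):
        return "csv"
    raise ValueError(f"cannot infer format of {path!r}; pass format= explicitly")


def _check_duplicates(ids: np.ndarray, what: str) -> None:
    uniq, counts = np.unique(ids, return_counts=True)
    dups = uniq[counts > 1]
    if len(dups):
        raise ValueError(f"duplicate {what}: {', '.join(dups[:10])}")


def read_spot_table(path: str, format: str | None = None) -> SpotTable:
    """Read a :class:`SpotTable` from ``path``.

    ``format`` is one of ``{"h5ad", "mtx", "csv"}``; inferred from the path
    when omitted. Raw values are preserved exactly as stored.
    """
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        import anndata as ad

        return SpotTable.from_anndata(ad.read_h5ad(path))
    if fmt in ("mtx", "mtx+positions"):
        return _read_mtx_dir(path)
    if fmt == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_csv(path: str) -> SpotTable:
    sep = "\t" if path.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns)
    id_col = cols[0]
    for coord in ("x", "y"):
        if coord not in cols:
            raise ValueError(f"missing coordinate column {coord!r} in {path}")
    spot_ids = df[id_col].astype(str).to_numpy()
    _check_duplicates(spot_ids, "spot barcodes")
    meta = {id_col, "x", "y", "annotation", "is_interpolated"}
    gene_cols = [c for c in cols if c not in meta]
    return SpotTable(
        expr=df[gene_cols].to_numpy(dtype=float),
        spot_ids=spot_ids,
        gene_ids=np.asarray(gene_cols),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        is_interpolated=(
            df["is_interpolated"].to_numpy(dtype=bool)
            if "is_interpolated" in cols
            else None
        ),
        annotation=(
            df["annotation"].astype(str).to_numpy() if "annotation" in cols else None
        ),
    )


def _find_positions_file(path: str) -> str:
    for name in ("tissue_positions.csv", "tissue_positions_list.csv", "positions.csv"):
        cand = os.path.join(path, name)
        if os.path.exists(cand):
            return cand
    raise ValueError(f"no tissue_positions CSV found in {path}")


def _read_mtx_dir(path: str) -> SpotTable:
    from scipy.io import mmread

    matrix = mmread(os.path.join(path, "matrix.mtx"))
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].astype(str).to_numpy()
    features = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t", header=None)
    gene_ids = features.iloc[:, 0].astype(str).to_numpy()

    pos_path = _find_positions_file(path)
    pos = pd.read_csv(pos_path)
    if "barcode" not in pos.columns:
        # headerless space-ranger v1 layout
        pos = pd.read_csv(pos_path, header=None, names=_POSITION_COLUMNS)
    missing = [c for c in ("barcode", "pxl_row", "pxl_col") if c not in pos.columns]
    if missing:
        raise ValueError(
            f"tissue positions file lacks required column(s): {', '.join(missing)}"
        )
    _check_duplicates(barcodes, "barcodes")
    pos = pos.set_index(pos["barcode"].astype(str))
    absent = [b for b in barcodes if b not in pos.index]
    if absent:
        raise ValueError(f"barcodes missing from positions file: {absent[:10]}")
    pos = pos.loc[barcodes]

    expr = np.asarray(matrix.todense(), dtype=float).T  # features x barcodes -> spots x genes
    keep = (
        pos["in_tissue"].to_numpy(dtype=int) == 1
        if "in_tissue" in pos.columns
        else np.ones(len(barcodes), dtype=bool)
    )
    if not np.all(keep):
        warnings.warn(f"dropping {int((~np.asarray(keep, bool)).sum())} spots with in_tissue=0")
    keep = np.asarray(keep, dtype=bool)
    coords = np.column_stack(
        [pos["pxl_col"].to_numpy(dtype=float), pos["pxl_row"].to_numpy(dtype=float)]
    )
    return SpotTable(
        expr=expr[keep],
        spot_ids=barcodes[keep],
        gene_ids=gene_ids,
        coords=coords[keep],
    )


def read_reference(path: str):
    """Read a single-cell reference (cells x genes + cell-type labels).

    Accepts an h5ad with ``obs['cell_type']`` or a CSV with a ``cell_type``
    column and one column per gene.
    """
    from .containers import ReferenceSet

    if path.endswith(".h5ad"):
        import anndata as ad
        import scipy.sparse as sp

        adata = ad.read_h5ad(path)
        if "cell_type" not in adata.obs:
            raise ValueError("reference h5ad lacks obs['cell_type']")
        X = adata.X
        if sp.issparse(X):
            X = X.toarray()
        return ReferenceSet(
            expr=np.asarray(X, dtype=float),
            gene_ids=np.asarray(adata.var_names, dtype=str),
            cell_type=np.asarray(adata.obs["cell_type"], dtype=str),
        )
    sep = "\t" if path.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    if "cell_type" not in df.columns:
        raise ValueError("reference table lacks a 'cell_type' column")
    gene_cols = [c for c in df.columns if c != "cell_type"]
    return ReferenceSet(
        expr=df[gene_cols].to_numpy(dtype=float),
        gene_ids=np.asarray(gene_cols),
        cell_type=df["cell_type"].astype(str).to_numpy(),
    )


def write_spot_table(table: SpotTable, path: str, format: str | None = None) -> None:
    """Write ``table`` to ``path`` as h5ad or flat CSV."""
    fmt = format or _infer_format(path)
    if fmt == "h5ad":
        table.to_anndata().write_h5ad(path)
        return
    if fmt == "csv":
        sep = "\t" if path.endswith(".tsv") else ","
        df = pd.DataFrame(table.expr, columns=table.gene_ids)
        df.insert(0, "spot_id", table.spot_ids)
        df.insert(1, "x", table.coords[:, 0])
        df.insert(2, "y", table.coords[:, 1])
        df["is_interpolated"] = table.is_interpolated
        if table.annotation is not None:
            df["annotation"] = table.annotation
        df.to_csv(path, sep=sep, index=False)
        return
    raise ValueError(f"unknown format {fmt!r}")
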