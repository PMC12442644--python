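"""Per-spot cell-type composition.

Either load an external deconvolution result (CSV/TSV with a spot-id
column) or estimate one with the built-in baseline: non-negative least
squares of each spot's expression against per-type signature vectors,
followed by normalization to the simplex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import ReferenceSet, SpotTable

__all__ = [
    "ProportionMatrix",
    "SignatureMatrix",
    "load_proportions",
    "signature_matrix",
    "nnls_deconvolve",
    "write_proportions",
]


@dataclass
class ProportionMatrix:
    """Spot x cell-type composition; every row lies on the simplex."""

    values: np.ndarray
    spot_ids: np.ndarray
    type_names: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.spot_ids = np.asarray(self.spot_ids, dtype=str)
        self.type_names = np.asarray(self.type_names, dtype=str)
        if self.values.shape != (len(self.spot_ids), len(self.type_names)):
            raise ValueError("values shape does not match spot_ids x type_names")
        if np.any(self.values < 0):
            raise ValueError("proportions must be non-negative")
        sums = self.values.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError("proportion rows must sum to 1 (within 1e-9)")

    @property
    def n_spots(self) -> int:
        return self.values.shape[0]


@dataclass
class SignatureMatrix:
    """Cell-type x gene signature profiles (mean preprocessed expression)."""

    values: np.ndarray
    type_names: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.type_names = np.asarray(self.type_names, dtype=str)
        self.gene_ids = np.asarray(self.gene_ids, dtype=str)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signatures must be finite")
        if len(self.type_names) < 2:
            raise ValueError("need at least 2 cell types")
        if self.values.shape != (len(self.type_names), len(self.gene_ids)):
            raise ValueError("values shape does not match type_names x gene_ids")


def load_proportions(path: str, table: SpotTable) -> ProportionMatrix:
    """Read a proportions CSV/TSV and align its rows to ``table``.

    The first column (or a column named ``spot_id``) carries spot ids;
    remaining columns are cell types. Rows whose sums deviate from 1 by at
    most 1% are renormalized; larger deviations are an error.
    """
    sep = "\t" if path.endswith(".tsv") else ","
    df = pd.read_csv(path, sep=sep)
    id_col = "spot_id" if "spot_id" in df.columns else df.columns[0]
    df[id_col] = df[id_col].astype(str)
    df = df.set_index(id_col)
    missing = [s for s in table.spot_ids if s not in df.index]
    if missing:
        raise ValueError(
            f"{len(missing)} spot(s) missing from proportions file: {missing[:10]}"
        )
    df = df.loc[table.spot_ids]
    values = df.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("proportions file contains negative entries")
    sums = values.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 0.01):
        bad = table.spot_ids[np.abs(sums - 1.0) > 0.01]
        raise ValueError(
            f"proportion rows deviate from sum 1 by more than 1%: {bad[:10]}"
        )
    values = values / sums[:, None]
    return ProportionMatrix(
        values=values,
        spot_ids=table.spot_ids.copy(),
        type_names=df.columns.to_numpy(dtype=str),
    )


def signature_matrix(ref: ReferenceSet) -> SignatureMatrix:
    """Per-type mean expression over the reference cells."""
    types = np.unique(ref.cell_type)
    rows = []
    for t in types:
        mask = ref.cell_type == t
        if not mask.any():
            raise ValueError(f"cell type {t!r} has no cells")
        rows.append(ref.expr[mask].mean(axis=0))
    return SignatureMatrix(
        values=np.vstack(rows), type_names=types, gene_ids=ref.gene_ids.copy()
    )


def nnls_deconvolve(table: SpotTable, sig: SignatureMatrix) -> ProportionMatrix:
    """Per-spot NNLS of expression on signatures, normalized to the simplex.

    Solves min ||x - w^T S||^2 s.t. w >= 0 for each spot; an all-zero
    solution falls back to the uniform composition.
    """
    if table.n_genes != len(sig.gene_ids) or not np.array_equal(
        table.gene_ids, sig.gene_ids
    ):
        raise ValueError("spot table and signatures must share the same gene space")
    if np.linalg.matrix_rank(sig.values) < sig.values.shape[0]:
        warnings.warn("signature matrix is rank-deficient; solutions may be non-unique")
    A = sig.values.T  # genes x types
    n_types = sig.values.shape[0]
    out = np.empty((table.n_spots, n_types))
    for i in range(table.n_spots):
        w, _ = nnls(A, table.expr[i])
        s = w.sum()
        out[i] = w / s if s > 0 else np.full(n_types, 1.0 / n_types)
    return ProportionMatrix(
        values=out, spot_ids=table.spot_ids.copy(), type_names=sig.type_names.copy()
    )


def write_proportions(props: ProportionMatrix, path: str) -> None:
    """Write a proportions CSV (spot_id + one column per type)."""
    df = pd.DataFrame(props.values, columns=props.type_names)
    df.insert(0, "spot_id", props.spot_ids)
    df.to_csv(path, index=False)
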