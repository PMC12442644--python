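"""Gap geometry on a hexagonal spot lattice.

On spot-based platforms with a honeycomb layout, every three mutually
adjacent spots enclose a triangular tissue region whose transcriptome is
never measured. This module enumerates those triangles and computes their
centroids, which become the coordinates of interpolated pseudo-spots.

Triangles are found by Delaunay triangulation of the spot centers, keeping
only triangles whose longest edge does not exceed ``pitch_factor`` times the
modal nearest-neighbor distance — on an ideal lattice this is exactly the
set of triples of mutually adjacent spots, and it stays robust to missing
spots at tissue boundaries.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

__all__ = [
    "GapRegion",
    "centroid",
    "modal_nn_distance",
    "partition_gaps",
    "unmeasured_fraction",
    "write_gaps_csv",
]


@dataclass(frozen=True)
class GapRegion:
    """A triangular gap: three mutually adjacent spot indices + centroid."""

    vertex_indices: tuple
    centroid: tuple

    def __post_init__(self):
        object.__setattr__(
            self, "vertex_indices", tuple(int(v) for v in self.vertex_indices)
        )
        object.__setattr__(self, "centroid", tuple(float(c) for c in self.centroid))


def centroid(region_vertices) -> np.ndarray:
    """Arithmetic mean of three coordinate pairs."""
    pts = np.asarray(region_vertices, dtype=float)
    if pts.shape != (3, 2):
        raise ValueError("expected exactly 3 coordinate pairs")
    if not np.all(np.isfinite(pts)):
        raise ValueError("vertex coordinates must be finite")
    return pts.mean(axis=0)


def modal_nn_distance(coords: np.ndarray) -> float:
    """Most common nearest-neighbor distance (rounded to 6 decimals)."""
    coords = np.asarray(coords, dtype=float)
    tree = cKDTree(coords)
    dist, _ = tree.query(coords, k=2)
    nn = np.round(dist[:, 1], 6)
    values, counts = np.unique(nn, return_counts=True)
    return float(values[np.argmax(counts)])


def _triangle_ok(pts: np.ndarray, max_edge: float, area_tol: float):
    """(within edge threshold, non-degenerate) for one triangle."""
    e = [np.linalg.norm(pts[a] - pts[b]) for a, b in ((0, 1), (0, 2), (1, 2))]
    if max(e) > max_edge:
        return False, True
    area = 0.5 * abs(
        (pts[1, 0] - pts[0, 0]) * (pts[2, 1] - pts[0, 1])
        - (pts[2, 0] - pts[0, 0]) * (pts[1, 1] - pts[0, 1])
    )
    return True, area > area_tol


def partition_gaps(coords: np.ndarray, pitch_factor: float = 1.2) -> list:
    """Enumerate triangular gap regions between mutually adjacent spots.

    Returns a list of :class:`GapRegion`, sorted by vertex-index triple so
    the output is invariant to spot input order up to index relabeling.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("coords must be an (n, 2) array")
    if coords.shape[0] < 3:
        raise ValueError("at least 3 spots are required to partition gaps")

    d_nn = modal_nn_distance(coords)
    if d_nn == 0:
        raise ValueError("duplicate spot coordinates: modal neighbor distance is 0")
    tree = cKDTree(coords)
    all_nn = tree.query(coords, k=2)[0][:, 1]
    irregular = np.mean(np.abs(all_nn - d_nn) > 0.25 * d_nn)
    if irregular > 0.2:
        warnings.warn(
            f"lattice looks irregular: {irregular:.0%} of nearest-neighbor "
            "distances deviate >25% from the modal pitch"
        )

    try:
        tri = Delaunay(coords)
    except QhullError:
        warnings.warn("degenerate (collinear) spot layout; no gap regions found")
        return []

    max_edge = pitch_factor * d_nn
    area_tol = 1e-9 * d_nn**2
    seen = set()
    regions = []
    n_degenerate = 0
    for simplex in tri.simplices:
        key = tuple(sorted(int(v) for v in simplex))
        if key in seen:
            continue
        seen.add(key)
        pts = coords[list(key)]
        ok, nondegenerate = _triangle_ok(pts, max_edge, area_tol)
        if not ok:
            continue
        if not nondegenerate:
            n_degenerate += 1
            continue
        regions.append(GapRegion(key, tuple(centroid(pts))))
    if n_degenerate:
        warnings.warn(f"skipped {n_degenerate} degenerate (collinear) triangle(s)")
    regions.sort(key=lambda r: r.vertex_indices)
    return regions


def unmeasured_fraction(n_spots: int, spot_diameter: float, slide_side: float) -> float:
    """Fraction of a square slide not covered by circular capture spots.

    ``1 - n_spots * pi * (spot_diameter / 2)**2 / slide_side**2``, clipped
    to [0, 1]. For a standard 6.5 mm slide with 4992 spots of 55 um
    diameter this is ~0.72, i.e. roughly 70% of the tissue area falls
    between spots.
    """
    if spot_diameter <= 0 or slide_side <= 0:
        raise ValueError("spot_diameter and slide_side must be positive")
    if n_spots < 0:
        raise ValueError("n_spots must be non-negative")
    covered = n_spots * math.pi * (spot_diameter / 2.0) ** 2 / slide_side**2
    return float(min(1.0, max(0.0, 1.0 - covered)))


def write_gaps_csv(regions, coords, path: str) -> None:
    """Write gap regions as CSV (gap_id, v1, v2, v3, x, y) for provenance."""
    import pandas as pd

    rows = [
        {
            "gap_id": f"gap_{i}",
            "v1": r.vertex_indices[0],
            "v2": r.vertex_indices[1],
            "v3": r.vertex_indices[2],
            "x": r.centroid[0],
            "y": r.centroid[1],
        }
        for i, r in enumerate(regions)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
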