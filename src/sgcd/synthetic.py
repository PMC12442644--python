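"""Synthetic hexagonal-lattice slides with known ground truth.

Emulates a spot-based platform: spots on a honeycomb lattice with a
100-unit center-to-center pitch, contiguous spatial domains (horizontal
bands by default), domain-specific expression programs (disjoint marker
sets elevated in log space, Gaussian noise, exponentiated and rounded to
counts) and domain-specific Dirichlet cell-type compositions. Every
generator is a pure function of its configuration seed.

The generator targets log-space expression structure directly rather than
an explicit negative-binomial count model: downstream stages consume
log-normalized data, so domain separability is controlled in the space
that matters, in units of the noise standard deviation (``expr_effect``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil, sqrt

import numpy as np

from .containers import ReferenceSet, SpotTable
from .proportions import ProportionMatrix

__all__ = [
    "SimulationConfig",
    "SlideSimulation",
    "make_hex_lattice",
    "make_domains",
    "simulate_expression",
    "simulate_proportions",
    "simulate_reference",
    "simulate_slide",
]

_BASE_LOG_MEAN = 1.0  # baseline log expression; exp(1) ~ 2.7 counts


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic slide."""

    rows: int = 20
    cols: int = 20
    pitch: float = 100.0
    n_genes: int = 200
    n_domains: int = 4
    n_cell_types: int = 8
    domain_pattern: str = "bands"
    expr_effect: float = 3.0  # marker elevation in units of noise_sd
    noise_sd: float = 1.0
    dirichlet_within: float = 20.0
    dirichlet_between: float = 1.0
    cells_per_type: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice dims must be positive")
        if self.rows * self.cols < self.n_domains:
            raise ValueError("fewer spots than domains")
        if self.n_genes < self.n_domains:
            raise ValueError("need at least one gene per domain")
        if self.n_cell_types < self.n_domains:
            raise ValueError("need at least one cell type per domain")
        if self.pitch <= 0 or self.noise_sd < 0 or self.expr_effect < 0:
            raise ValueError("pitch must be positive, effects non-negative")
        if min(self.dirichlet_within, self.dirichlet_between) <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.domain_pattern not in ("bands", "blocks", "voronoi"):
            raise ValueError(f"unknown domain pattern {self.domain_pattern!r}")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def make_hex_lattice(config: SimulationConfig) -> np.ndarray:
    """Honeycomb coordinates: odd rows offset by pitch/2, row spacing pitch*sqrt(3)/2."""
    r = np.arange(config.rows)
    c = np.arange(config.cols)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    x = cc * config.pitch + (rr % 2) * (config.pitch / 2.0)
    y = rr * (config.pitch * np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)


def make_domains(coords: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Ground-truth domain label per spot.

    ``bands`` — horizontal strips of near-equal row counts; ``blocks`` —
    a grid of rectangular tiles; ``voronoi`` — nearest of n_domains random
    seed points.
    """
    coords = np.asarray(coords, dtype=float)
    row_h = config.pitch * np.sqrt(3.0) / 2.0
    if config.domain_pattern == "bands":
        row_idx = np.rint(coords[:, 1] / row_h).astype(int)
        return (row_idx * config.n_domains) // config.rows
    if config.domain_pattern == "blocks":
        g = ceil(sqrt(config.n_domains))
        row_idx = np.rint(coords[:, 1] / row_h).astype(int)
        col_idx = np.floor(coords[:, 0] / config.pitch).astype(int)
        rb = (row_idx * g) // config.rows
        cb = np.minimum((col_idx * g) // config.cols, g - 1)
        return (rb * g + cb) % config.n_domains
    # voronoi
    rng = _rng(config, 0)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    seeds = rng.uniform(lo, hi, size=(config.n_domains, 2))
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)


def _domain_means(config: SimulationConfig) -> np.ndarray:
    """Log-space mean vector per domain: disjoint elevated marker blocks."""
    rng = _rng(config, 1)
    perm = rng.permutation(config.n_genes)
    block = config.n_genes // config.n_domains
    mu = np.full((config.n_domains, config.n_genes), _BASE_LOG_MEAN)
    lift = config.expr_effect * config.noise_sd
    for d in range(config.n_domains):
        markers = perm[d * block : (d + 1) * block]
        mu[d, markers] += lift
    return mu


def simulate_expression(labels: np.ndarray, config: SimulationConfig,
                        coords: np.ndarray | None = None) -> SpotTable:
    """Counts = rint(exp(mu_domain + N(0, noise_sd))) per spot and gene."""
    labels = np.asarray(labels, dtype=int)
    if coords is None:
        coords = make_hex_lattice(config)
    mu = _domain_means(config)
    rng = _rng(config, 2)
    log_expr = mu[labels] + rng.normal(0.0, config.noise_sd,
                                       size=(len(labels), config.n_genes))
    counts = np.rint(np.exp(log_expr))
    return SpotTable(
        expr=counts,
        spot_ids=np.array([f"spot_{i:04d}" for i in range(len(labels))]),
        gene_ids=np.array([f"gene_{j:04d}" for j in range(config.n_genes)]),
        coords=np.asarray(coords, dtype=float),
        annotation=labels.astype(str),
    )


def _dominant_types(config: SimulationConfig) -> list:
    """Round-robin assignment of cell types to domains (disjoint, exhaustive)."""
    return [
        [t for t in range(config.n_cell_types) if t % config.n_domains == d]
        for d in range(config.n_domains)
    ]


def simulate_proportions(labels: np.ndarray, config: SimulationConfig
                         ) -> ProportionMatrix:
    """Domain-specific Dirichlet cell-type compositions per spot."""
    labels = np.asarray(labels, dtype=int)
    rng = _rng(config, 3)
    dom = _dominant_types(config)
    alphas = np.full((config.n_domains, config.n_cell_types),
                     config.dirichlet_between)
    for d in range(config.n_domains):
        alphas[d, dom[d]] = config.dirichlet_within
    values = np.empty((len(labels), config.n_cell_types))
    for i, lab in enumerate(labels):
        values[i] = rng.dirichlet(alphas[lab])
    values /= values.sum(axis=1, keepdims=True)
    return ProportionMatrix(
        values=values,
        spot_ids=np.array([f"spot_{i:04d}" for i in range(len(labels))]),
        type_names=np.array([f"type_{t}" for t in range(config.n_cell_types)]),
    )


def type_log_means(config: SimulationConfig) -> np.ndarray:
    """Log-space signature per cell type, consistent with the spot markers.

    A type dominant in domain d shares that domain's mean and additionally
    elevates a private slice of the domain's marker block, so types within
    a domain stay distinguishable.
    """
    mu_dom = _domain_means(config)
    rng = _rng(config, 4)
    perm = rng.permutation(config.n_genes)
    sig = np.empty((config.n_cell_types, config.n_genes))
    dom = _dominant_types(config)
    slice_len = max(1, config.n_genes // (4 * config.n_cell_types))
    lift = config.expr_effect * config.noise_sd
    pos = 0
    for d in range(config.n_domains):
        for t in dom[d]:
            sig[t] = mu_dom[d]
            own = perm[pos : pos + slice_len]
            sig[t, own] += 0.5 * lift
            pos += slice_len
    return sig


def simulate_reference(config: SimulationConfig) -> ReferenceSet:
    """Single-cell reference: ``cells_per_type`` cells per type around its signature."""
    sig = type_log_means(config)
    rng = _rng(config, 5)
    cells = []
    types = []
    for t in range(config.n_cell_types):
        log_expr = sig[t] + rng.normal(
            0.0, config.noise_sd, size=(config.cells_per_type, config.n_genes)
        )
        cells.append(np.rint(np.exp(log_expr)))
        types.extend([f"type_{t}"] * config.cells_per_type)
    return ReferenceSet(
        expr=np.vstack(cells),
        gene_ids=np.array([f"gene_{j:04d}" for j in range(config.n_genes)]),
        cell_type=np.array(types),
    )


@dataclass
class SlideSimulation:
    """One simulated slide with every piece of ground truth."""

    table: SpotTable
    labels: np.ndarray
    proportions: ProportionMatrix
    reference: ReferenceSet
    config: SimulationConfig = field(repr=False, default=None)


def simulate_slide(config: SimulationConfig | None = None) -> SlideSimulation:
    """Generate a complete slide: lattice, domains, counts, compositions, reference."""
    config = config or SimulationConfig()
    coords = make_hex_lattice(config)
    labels = make_domains(coords, config)
    table = simulate_expression(labels, config, coords)
    props = simulate_proportions(labels, config)
    ref = simulate_reference(config)
    return SlideSimulation(table=table, labels=labels, proportions=props,
                           reference=ref, config=config)
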