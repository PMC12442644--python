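import numpy as np
import pytest

from sgcd.containers import SpotTable
from sgcd.synthetic import SimulationConfig, simulate_slide


@pytest.fixture(scope="session")
def small_sim():
    """An 8x8 slide with 60 genes: cheap, fully deterministic ground truth."""
    return simulate_slide(SimulationConfig(rows=8, cols=8, n_genes=60, seed=0))


@pytest.fixture()
def tiny_table():
    """Three spots, four genes, hand-written values."""
    return SpotTable(
        expr=np.array([[1.0, 0.0, 2.0, 3.0],
                       [0.0, 4.0, 1.0, 1.0],
                       [2.0, 2.0, 2.0, 2.0]]),
        spot_ids=["s1", "s2", "s3"],
        gene_ids=["g1", "g2", "g3", "g4"],
        coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.9]]),
    )


def hex_lattice(rows, cols, pitch=100.0):
    r = np.arange(rows)
    c = np.arange(cols)
    rr, cc = np.meshgrid(r, c, indexing="ij")
    x = cc * pitch + (rr % 2) * (pitch / 2.0)
    y = rr * (pitch * np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel(), y.ravel()]).astype(float)
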