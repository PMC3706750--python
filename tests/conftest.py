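import numpy as np
import pytest

from plantvem.config import GeometryConfig, MeshConfig, SimConfig, SolverConfig
from plantvem.meshing import triangulate_tissue
from plantvem.tissue import build_synthetic_root


@pytest.fixture
def small_config():
    """Two files, three-ish cells per file: a tissue small enough for
    brute-force oracles."""
    return SimConfig(
        geometry=GeometryConfig(n_files=2, total_length=150.0, min_cell_length=50.0),
        mesh=MeshConfig(max_area=250.0),
        seed=7,
    )


@pytest.fixture
def small_tissue(small_config):
    g = small_config.geometry
    return build_synthetic_root(g.n_files, g.file_height, g.total_length,
                                g.min_cell_length, seed=small_config.seed,
                                config=small_config)


@pytest.fixture
def small_meshed_tissue(small_tissue):
    return triangulate_tissue(small_tissue, (20.0, 250.0))


@pytest.fixture
def single_cell_tissue():
    """One isolated 100×20 μm cell with default (Table-style) parameters."""
    cfg = SimConfig(
        geometry=GeometryConfig(n_files=1, total_length=100.0, min_cell_length=100.0),
        mesh=MeshConfig(max_area=50.0),
        seed=0,
    )
    t = build_synthetic_root(1, 20.0, 100.0, 100.0, seed=0, config=cfg)
    return triangulate_tissue(t, (20.0, 50.0))


def rot(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])
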