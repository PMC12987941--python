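import numpy as np
import pytest

import hemograph as hg


@pytest.fixture(scope="session")
def tube_coarse():
    """Radius-2 mm, length-6 mm tube at h = 0.5 (fast, ~1k nodes)."""
    return hg.make_tube_mesh(radius=2.0, length=6.0, h=0.5)


@pytest.fixture(scope="session")
def tube_h03():
    """Radius-2 mm tube at the reference 0.3 mm element size."""
    return hg.make_tube_mesh(radius=2.0, length=6.0, h=0.3)


@pytest.fixture(scope="session")
def waveform():
    return hg.InflowWaveform()


@pytest.fixture(scope="session")
def poiseuille_traj(tube_coarse, waveform):
    """Quasi-steady Poiseuille flow over a short window, dt = 0.01 s."""
    return hg.make_analytic_trajectory(
        tube_coarse, waveform, dt=0.01, n_cycles=0.1
    )


@pytest.fixture(scope="session")
def single_tet():
    """One positively-oriented unit tetrahedron, classified by hand."""
    mesh = hg.VolumetricMesh(
        positions=np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        ),
        tetrahedra=np.array([[0, 1, 2, 3]]),
    ).orient()
    mesh.node_type = np.full(4, hg.WALL)
    return mesh
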