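import numpy as np
import pytest

from tistim.leadfield import (
    ElectrodeLayout,
    LeadField,
    compute_spherical_leadfield,
    cortex_shell_nodes,
    fibonacci_cap_layout,
    generate_random_leadfield,
)
from tistim.sphere import SphereModel


@pytest.fixture(scope="session")
def sphere_lf() -> LeadField:
    """400-node volumetric-shell cortex on the default four-shell sphere.

    Shared session fixture: the depth anchors only make sense when cortex
    nodes span a range of depths.
    """
    model = SphereModel()
    layout = fibonacci_cap_layout(69, scalp_radius=model.scalp_radius)
    nodes = cortex_shell_nodes(400, inner_fraction=0.35, seed=0)
    return compute_spherical_leadfield(model, layout, nodes)


@pytest.fixture(scope="session")
def rand_lf() -> LeadField:
    return generate_random_leadfield(n_nodes=120, n_electrodes=10, seed=7)


@pytest.fixture()
def make_leadfield():
    """Factory for hand-built lead fields with arbitrary matrices."""

    def _make(matrix: np.ndarray) -> LeadField:
        matrix = np.asarray(matrix, dtype=float)
        n, m_free = matrix.shape
        M = m_free + 1
        pos = np.zeros((M, 3))
        pos[:, 2] = 1.0
        pos[:, 0] = np.linspace(-0.5, 0.5, M)
        pos = pos / np.linalg.norm(pos, axis=1, keepdims=True) * 92.0
        layout = ElectrodeLayout(positions=pos,
                                 labels=tuple(f"E{i}" for i in range(M)))
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * 10.0
        coords[:, 2] = 50.0
        normals = np.tile([0.0, 0.0, 1.0], (n, 1))
        return LeadField(matrix=matrix, node_coords=coords,
                         node_normals=normals, layout=layout,
                         provenance="synthetic test fixture")

    return _make
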