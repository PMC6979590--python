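import numpy as np
import pytest

from porofem.constitutive import MaterialParams
from porofem.mesh import Mesh, _finish_mesh


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def soft_params():
    """Barrier-regularized material with a residual reference stress."""
    return MaterialParams.from_young_poisson(
        1000.0, 0.15, phi0=0.9, k0=1e-3, upsilon=1e-3
    )


@pytest.fixture
def single_tet():
    coords = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = Mesh(ref_coords=coords, cells=np.array([[0, 1, 2, 3]]), cell_type="tet4")
    return _finish_mesh(mesh, lambda fc: "boundary")


def random_admissible_F(rng, phi0=0.9, scale=0.2):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 1.0 - phi0 + 0.05:
            return F
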