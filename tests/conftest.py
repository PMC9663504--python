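import numpy as np
import pytest

from bulkybone.fem import Material
from bulkybone.mesh import (CylinderSpec, DEFAULT_PARTITION,
                            assign_axial_regions, build_cylinder_mesh)


@pytest.fixture(scope="session")
def material():
    return Material(young_modulus=1.0, poisson_ratio=0.40)


@pytest.fixture(scope="session")
def small_mesh():
    """~1.4k tets; fast enough for per-test FEM work."""
    return build_cylinder_mesh(CylinderSpec(10.0, 1.0, 12, 3, 8))


@pytest.fixture(scope="session")
def small_mesh_regions(small_mesh):
    return assign_axial_regions(small_mesh, DEFAULT_PARTITION)


@pytest.fixture(scope="session")
def medium_mesh_regions():
    """~5k tets, the scale used for linearity/reciprocity checks."""
    m = build_cylinder_mesh(CylinderSpec(10.0, 1.0, 20, 5, 12))
    return assign_axial_regions(m, DEFAULT_PARTITION)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
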