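import numpy as np
import pytest

from tetrasim.biomodel import DiffusionRule, Reaction, VolumeSystem, build_model
from tetrasim.mesh_core import build_tetmesh, make_compartment
from tetrasim.synthetic_geometry import box_mesh, nested_sphere_mesh

UNIT_TET_VERTS = np.array(
    [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
)


@pytest.fixture
def rng():
    return np.random.Generator(np.random.PCG64(20240601))


@pytest.fixture
def unit_tet_mesh():
    return build_tetmesh(UNIT_TET_VERTS, [(0, 1, 2, 3)])


@pytest.fixture
def two_tet_mesh():
    """Two tets glued along the face (1, 2, 3)."""
    verts = np.vstack([UNIT_TET_VERTS, [[1.0, 1.0, 1.0]]])
    return build_tetmesh(verts, [(0, 1, 2, 3), (1, 2, 3, 4)])


@pytest.fixture
def small_box():
    """1 um cube, 3 divisions per axis: 162 tets."""
    return box_mesh((1e-6, 1e-6, 1e-6), (3, 3, 3))


@pytest.fixture
def nested_mesh():
    return nested_sphere_mesh(1e-6, 0.4e-6, 1e-6 / 8)


@pytest.fixture
def diffusion_model():
    """One diffusible species in volume system "vsys"."""
    return build_model(
        species=["A"],
        diffusion_rules=[DiffusionRule("dA", "A", 1e-11)],
        volume_systems=[VolumeSystem("vsys", diffusion_rules=("dA",))],
    )


@pytest.fixture
def decay_model():
    """A -> B at 1/s in volume system "vsys"."""
    return build_model(
        species=["A", "B"],
        reactions=[Reaction("decay", ("A",), ("B",), 1.0)],
        volume_systems=[VolumeSystem("vsys", reactions=("decay",))],
    )


@pytest.fixture
def bar_with_compartment(diffusion_model):
    """Thin bar mesh with a single compartment carrying "vsys"."""
    mesh = box_mesh((20e-6, 0.4e-6, 0.4e-6), (100, 2, 2))
    make_compartment(mesh, "bar", range(mesh.n_tets), ["vsys"])
    return mesh
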