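import dataclasses

import numpy as np
import pytest
import trimesh

import platemetry as pm
from platemetry.synthetic_fixtures import PhantomSpec


@pytest.fixture(scope="session")
def default_spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def default_phantom(default_spec):
    """(mesh, landmarks, truth) of the default phantom appliance."""
    return pm.make_phantom(default_spec)


@pytest.fixture(scope="session")
def default_result(default_phantom):
    """Full pipeline products for the default phantom (computed once)."""
    mesh, landmarks, _ = default_phantom
    return pm.measure_plate_detailed(mesh, landmarks)


@pytest.fixture(scope="session")
def rotated_phantom(default_spec):
    """The same phantom under a known rigid motion."""
    spec = dataclasses.replace(
        default_spec, rotation_deg=(17.0, -9.0, 42.0), translation=(13.0, -7.0, 22.0)
    )
    return pm.make_phantom(spec)


@pytest.fixture()
def cube_soup():
    """A unit cube as unwelded facet soup (36 raw vertices, 12 faces)."""
    box = trimesh.creation.box(extents=[1.0, 1.0, 1.0])
    vertices = box.vertices[box.faces].reshape(-1, 3)
    faces = np.arange(36).reshape(-1, 3)
    return trimesh.Trimesh(vertices=vertices, faces=faces, process=False)


@pytest.fixture()
def canonical_frame():
    """Frame with the base plane z = 0, normal pointing down (-z)."""
    from platemetry.reference_frame import ReferenceFrame

    return ReferenceFrame(
        origin=np.zeros(3),
        normal=np.array([0.0, 0.0, -1.0]),
        sagittal=np.array([1.0, 0.0, 0.0]),
        mediolateral=np.array([0.0, 1.0, 0.0]),
        drop=20.0,
    )
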