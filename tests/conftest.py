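"""Shared fixtures: canonical meshes, phantoms and deterministic RNG."""
import numpy as np
import pytest
from hypothesis import settings

import osteoprint as op

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def unit_cube_mesh():
    """Closed unit cube, 12 triangles, outward winding (signed volume +1)."""
    v = np.array(
        [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
            [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
        ],
        dtype=float,
    )
    f = np.array(
        [
            [0, 2, 1], [0, 3, 2],  # bottom (-z)
            [4, 5, 6], [4, 6, 7],  # top (+z)
            [0, 1, 5], [0, 5, 4],  # -y
            [1, 2, 6], [1, 6, 5],  # +x
            [2, 3, 7], [2, 7, 6],  # +y
            [3, 0, 4], [3, 4, 7],  # -x
        ]
    )
    mesh = op.TriangleMesh(v, f)
    assert abs(mesh.volume() - 1.0) < 1e-12
    return mesh


@pytest.fixture(scope="session")
def ball_mesh():
    """Watertight sphere mesh, r = 8 mm at 1 mm sampling (~2.3k triangles)."""
    return op.extract_isosurface(op.sphere_distance_volume(8.0, 1.0), 0.0)


@pytest.fixture(scope="session")
def small_ball_mesh():
    """Coarser sphere (r = 6 mm at 1.5 mm) for corruption/repair loops."""
    return op.extract_isosurface(op.sphere_distance_volume(6.0, 1.5), 0.0)


@pytest.fixture(scope="session")
def box_mesh():
    """Asymmetric box solid (30 x 18 x 10 mm) for registration tests."""
    return op.extract_isosurface(op.box_distance_volume((15.0, 9.0, 5.0), 1.25), 0.0)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free femur/implant phantom volume plus analytic truth."""
    spec = op.femur_implant_phantom(noise_sd=0.0, streak_amplitude=0.0, seed=3)
    return op.generate_phantom(spec)
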