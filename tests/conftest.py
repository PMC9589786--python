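import numpy as np
import pytest

from spectromesh.meshing import TriMesh, build_mesh
from spectromesh.preprocess import Signal
from spectromesh.synthetic import generate_height_field_mesh, height_field_surface


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def flat_mesh():
    """8x8 constant-height grid mesh."""
    return generate_height_field_mesh("flat", 8)


@pytest.fixture
def bump_mesh():
    """16x16 Gaussian-bump mesh, moderately curved."""
    return generate_height_field_mesh("gaussian_bumps", 16, amplitude=0.5, seed=3)


@pytest.fixture
def square_fan_mesh():
    """Unit square split into 4 triangles around one interior vertex."""
    vertices = np.array(
        [
            [0.0, 0.0, 0.0],
            [1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.5, 0.5, 0.0],
        ]
    )
    triangles = np.array([[0, 1, 4], [1, 2, 4], [2, 3, 4], [3, 0, 4]])
    return TriMesh(vertices=vertices, triangles=triangles)


@pytest.fixture
def tone_signal():
    """One second of a clean 500 Hz tone at 4 kHz sampling."""
    rate = 4000.0
    t = np.arange(int(rate)) / rate
    return Signal(samples=np.sin(2 * np.pi * 500.0 * t), rate=rate, id="tone", group="g0")


def random_grid_mesh(N: int, amplitude: float, seed: int) -> TriMesh:
    return generate_height_field_mesh("random", N, amplitude=amplitude, seed=seed)
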