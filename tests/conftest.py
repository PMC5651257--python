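import numpy as np
import pytest

from morphocode import (
    SyntheticSpec,
    TriSurface,
    make_ground_truth_prior,
)


@pytest.fixture
def tetrahedron() -> TriSurface:
    vertices = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
    return TriSurface(vertices=vertices, faces=faces)


@pytest.fixture(scope="session")
def small_prior():
    """3-mode ground-truth prior on a 42-vertex ellipsoid (fast)."""
    return make_ground_truth_prior(
        SyntheticSpec(subdivisions=1, n_modes=3, seed=7)
    )


@pytest.fixture(scope="session")
def default_prior():
    """Default 5-mode ground-truth prior on the 162-vertex template."""
    return make_ground_truth_prior(SyntheticSpec(seed=2026))
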