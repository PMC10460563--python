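import numpy as np
import pytest

from bracketvol.fixtures import circle_image, rectangle_image
from bracketvol.silhouette_io import SilhouetteImage, extract_outline
from bracketvol.validation import sphere_errors, spheroid_errors


@pytest.fixture(scope="session")
def sphere_3000_errors():
    """Signed % errors of the n=2 model for a 3,000-px circle fixture
    (used by several accuracy tests; expensive, so computed once)."""
    return sphere_errors(3000)


@pytest.fixture(scope="session")
def spheroid_3000_errors():
    """Signed % errors of the n=2 model for a 5:1 ellipse, 3,000-px major
    axis."""
    return spheroid_errors(3000)


@pytest.fixture(scope="session")
def sphere_400_errors():
    return sphere_errors(400)


@pytest.fixture
def rect_trace():
    """Unsmoothed outline of a 300 x 150 px rectangle (sharp corners)."""
    img = rectangle_image(300, 150)
    return extract_outline(SilhouetteImage.from_array(img < 128))


@pytest.fixture
def circle_trace_500():
    """Outline of a filled circle of radius 500 px."""
    img = circle_image(1000)
    return extract_outline(SilhouetteImage.from_array(img < 128))


def cube_mesh():
    """Axis-aligned unit cube as 12 consistently wound triangles."""
    v = np.array([[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                 dtype=float)
    f = np.array([
        [0, 1, 3], [0, 3, 2],  # x = 0
        [4, 6, 7], [4, 7, 5],  # x = 1
        [0, 4, 5], [0, 5, 1],  # y = 0
        [2, 3, 7], [2, 7, 6],  # y = 1
        [0, 2, 6], [0, 6, 4],  # z = 0
        [1, 5, 7], [1, 7, 3],  # z = 1
    ])
    return v, f
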