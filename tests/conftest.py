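import numpy as np
import pytest

from adaptivetrack.geometry import Domain
from adaptivetrack.tree import build_tree, build_uniform_tree


def circle_sdf(center=(0.5, 0.5), radius=0.25):
    c = np.asarray(center)

    def phi(pts):
        return radius - np.linalg.norm(np.atleast_2d(pts) - c, axis=1)

    return phi


@pytest.fixture(scope="session")
def unit_domain_128():
    return Domain(pixel_counts=(128, 128), spacing=(1 / 128, 1 / 128))


@pytest.fixture(scope="session")
def circle_tree(unit_domain_128):
    """Whitney tree around a circle of radius 0.25 (interior positive)."""
    return build_tree(unit_domain_128, circle_sdf(), max_level=7, lip=1.2)


@pytest.fixture(scope="session")
def uniform_tree_64():
    return build_uniform_tree(Domain.for_image((64, 64)))


@pytest.fixture(scope="session")
def translation_pair():
    from adaptivetrack.synthetic import make_translation_pair
    return make_translation_pair((1.5, -0.5), seed=0)


@pytest.fixture(scope="session")
def vortex_short():
    from adaptivetrack.synthetic import VortexSpec, make_vortex_sequence
    spec = VortexSpec(n_frames=6, size=100, seed=0)
    return make_vortex_sequence(spec)
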