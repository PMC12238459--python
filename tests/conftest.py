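import numpy as np
import pytest

from voxdose.engine import EngineScene
from voxdose.lu177 import build_spectrum
from voxdose.phantom import (
    OrganDef,
    PhantomConfig,
    ResolutionSpec,
    Sphere,
    build_phantom,
)


def water_block(n: int = 40, voxel_mm: float = 0.5):
    """Homogeneous soft-tissue block phantom (body covers the whole grid)."""
    c = (n - 1) * voxel_mm / 2.0
    cfg = PhantomConfig(
        resolution=ResolutionSpec(shape=(n, n, n), voxel_size_mm=voxel_mm),
        body=OrganDef(
            "body", "soft", Sphere((c, c, c), n * voxel_mm), organ_class="body"
        ),
    )
    return build_phantom(cfg)


@pytest.fixture(scope="session")
def decay_data():
    return build_spectrum()


@pytest.fixture(scope="session")
def block_phantom():
    return water_block()


@pytest.fixture(scope="session")
def block_scene(block_phantom):
    return EngineScene(block_phantom)


@pytest.fixture(scope="session")
def lr_mouse():
    from voxdose.phantom import mouse_config

    return build_phantom(mouse_config("lr"))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
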