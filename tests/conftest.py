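import numpy as np
import pytest

from aclloc.phantom import PhantomSpec, generate_phantom
from aclloc.volio import Geometry, Volume


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom world for fast unit tests (not the stated defaults)."""
    return PhantomSpec(
        grid_shape=(32, 32, 16),
        spacing=(1.0, 1.0, 3.0),
        acl_length=24.0,
        acl_width=9.0,
        footprint_radius=4.0,
        gap_halfwidth=2.0,
        noise_sd=0.05,
    )


@pytest.fixture(scope="session")
def clean_spec(small_spec):
    from dataclasses import replace

    return replace(small_spec, noise_sd=0.0)


@pytest.fixture(scope="session")
def phantom_case(small_spec):
    return generate_phantom(small_spec, seed=7)


@pytest.fixture(scope="session")
def clean_case(clean_spec):
    return generate_phantom(clean_spec, seed=7)


@pytest.fixture
def identity_volume():
    rng = np.random.default_rng(0)
    geom = Geometry(spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))
    return Volume(data=rng.normal(size=(8, 8, 6)).astype(np.float32), geometry=geom)


@pytest.fixture
def aniso_geometry():
    return Geometry(spacing=(0.5, 0.5, 3.0), origin=(-10.0, 4.0, 2.5))
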