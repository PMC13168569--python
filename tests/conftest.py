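import numpy as np
import pytest

from foramct import (
    BinaryMask,
    PhantomSpec,
    VoxelGrid,
    generate_phantom,
    process,
    recovery_config,
)

ISO = (1.0, 1.0, 1.0)


def as_mask(data, spacing=ISO, name="Mask"):
    return BinaryMask(data=np.asarray(data, dtype=bool), spacing=spacing, name=name)


def as_grid(data, spacing=ISO, name="Raw"):
    return VoxelGrid(data=np.asarray(data), spacing=spacing, name=name)


@pytest.fixture(scope="session")
def small_spec():
    """A compact 3-chamber specimen used by most pipeline-level tests."""
    return PhantomSpec(n_chambers=3, r0_um=8.0, wall_um=4.0, rng_seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def small_products(small_spec, small_phantom):
    grid, _truth = small_phantom
    return process(grid, recovery_config(small_spec))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
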