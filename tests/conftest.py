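import numpy as np
import pytest

from petnorm import (
    PhantomSpec,
    VoxelImage,
    make_template_phantom,
    sample_population,
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-scale phantom geometry: 32^3 grid, brain scaled to fit."""
    return PhantomSpec(
        grid_shape=(32, 32, 32),
        brain_semi_axes_mm=(4.8, 3.6, 3.2),
        seed=0,
    )


@pytest.fixture(scope="session")
def small_template(small_spec) -> VoxelImage:
    return make_template_phantom(small_spec)


@pytest.fixture(scope="session")
def small_population(small_spec, small_template):
    """12 clean subjects (no perturbations, no lesions), fixed seed."""
    return sample_population(small_template, 12, small_spec, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_image(rng, shape=(7, 6, 5), unit="SUV", positive=True) -> VoxelImage:
    data = rng.random(shape) + (0.5 if positive else -0.5)
    return VoxelImage(data, 1.0, unit=unit)
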