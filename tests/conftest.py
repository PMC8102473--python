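import numpy as np
import pytest

from mcvbmd.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """A noise-free small phantom spec used across modules."""
    return PhantomSpec(
        grid_shape=(64, 64, 32),
        bone_radius_mm=(1.5, 1.2),
        shell_thickness_mm=0.35,
        axis_curvature=0.15,
        annotated_range=(8, 24),
        noise_sigma=0.0,
        n_distractors=1,
        seed=2,
    )


@pytest.fixture(scope="session")
def small_case(small_spec):
    """(volume, mask) for the small noise-free phantom."""
    return generate_phantom(small_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
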