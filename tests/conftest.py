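import numpy as np
import pytest

from neoseg.phantom import PhantomSpec, make_subject


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Coarse phantom grid (same field of view as the default profile) for
    fast unit tests."""
    return PhantomSpec(shape=(48, 48, 24), spacing=(2.0, 2.0, 4.0), seed=7)


@pytest.fixture(scope="session")
def small_subject(small_spec):
    return make_subject(small_spec, 11)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, bias-free, unperturbed subject: piecewise-constant
    intensities with exactly known geometry."""
    spec = PhantomSpec(
        shape=(48, 48, 24), spacing=(2.0, 2.0, 4.0),
        class_sd=0.0, noise_sd=0.0, bias_amplitude=0.0,
        shift_mm=0.0, rot_deg=0.0, seed=7,
    )
    return make_subject(spec, 5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
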