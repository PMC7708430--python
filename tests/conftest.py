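import numpy as np
import pytest

from panseg.synthetic import SyntheticSpec, generate_sample


@pytest.fixture(scope="session")
def default_sample():
    """One default 256x256 synthetic section, reused across read-only tests."""
    return generate_sample(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def gradient_sample():
    """A section with a strong staining gradient and mild noise."""
    return generate_sample(
        SyntheticSpec(
            image_height=160,
            image_width=160,
            unevenness_amplitude=0.4,
            noise_sigma=2.0,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
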