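import numpy as np
import pytest

from wsf.simgen import StomaFieldSpec, generate_sample


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_sample():
    """One 128x128 high-contrast field."""
    return generate_sample(StomaFieldSpec.desk(seed=7))


@pytest.fixture(scope="session")
def clean_field():
    """A full-size field with fixed 120x66 axis stomata, axis-aligned."""
    spec = StomaFieldSpec(n_stomata=8, long_axis_range=(120.0, 120.0),
                          short_axis_range=(66.0, 66.0),
                          orientation_jitter_deg=0.0, seed=5)
    return generate_sample(spec)
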