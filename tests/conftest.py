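import numpy as np
import pytest

from dynoct import PhantomSpec, TimeSeriesStack


@pytest.fixture()
def rng():
    return np.random.default_rng(20210)


@pytest.fixture()
def random_stack(rng):
    """Small random dB stack with realistic offsets (tests cancellation safety)."""
    data = 25.0 + 3.0 * rng.standard_normal((2, 32, 6, 5))
    return TimeSeriesStack(data=data, dt_ms=204.8)


@pytest.fixture()
def tiny_phantom_spec():
    """Coarse but fast two-compartment spheroid used by several suites."""
    return PhantomSpec(
        shape=(16, 40, 40),
        x_pitch_um=8.0,
        y_pitch_um=14.0,
        z_pitch_um=8.0,
        spheroid_radius_um=90.0,
        core_radius_um=55.0,
        rng_seed=42,
    )
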