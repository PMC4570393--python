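import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dcstools as d

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


def make_speckle(tau_c_bins: float, n: int, seed: int, f: float = 1.0, dt: float = 1e-6):
    """Simulated speckle intensity with an exponential field model."""
    cfg = d.SimulationConfig(
        duration=n * dt,
        bin_width=dt,
        seed=seed,
        coherent_fraction=f,
        field=d.FieldModel(tau_c=tau_c_bins * dt),
    )
    return d.simulate_intensity(cfg)


@pytest.fixture(scope="session")
def speckle_2e18():
    """One medium-size full-coherence speckle run shared across tests."""
    return make_speckle(tau_c_bins=100, n=2**18, seed=42)
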