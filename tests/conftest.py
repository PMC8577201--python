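import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rhizosim.engine import ScenarioConfig, run_sweep

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def tiny_cfg():
    """Coarse, short scenario for fast engine tests (seconds-scale suite)."""
    return ScenarioConfig(nx=10, ny=10, nz=12, h_cm=2.0, duration_d=4.0,
                          dt_d=0.5, seed=11)


@pytest.fixture(scope="session")
def reduced_sweep():
    """The reduced factorial (3 RHL x 2 RHD x 2 N x 2 f_T) on the default
    5 mm grid, shared by the simulator property and trend checks."""
    return run_sweep(
        rhl_levels=(0.0, 0.5, 1.0),
        rhd_levels=(100.0, 1000.0),
        n_levels=(62.4, 145.6),
        transpiration_levels=(0.25, 1.0),
        master_seed=42,
    )
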