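import numpy as np
import pytest

from fosplace.synthetic import GroupSpec, SimConfig, generate_session


@pytest.fixture(scope="session")
def small_session():
    """Small mixed-population expert session shared by read-only tests."""
    cfg = SimConfig(n_cells=20, n_trials=16)
    return cfg, generate_session(cfg, 123)


@pytest.fixture(scope="session")
def tuned_session():
    """Fully tuned, fully reliable, noiseless session for recovery tests."""
    cfg = SimConfig(
        n_cells=30,
        n_trials=20,
        noise_sd=0.0,
        groups={"high": GroupSpec(1.0, reliability_p=1.0, tuned_fraction=1.0)},
    )
    return cfg, generate_session(cfg, 7)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
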