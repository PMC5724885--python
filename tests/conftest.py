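import numpy as np
import pytest

from nirscal.simulate import SyntheticConfig, generate


@pytest.fixture(scope="session")
def coarse_dataset():
    """Moderate synthetic dataset on a 10 nm grid (fast to calibrate)."""
    cfg = SyntheticConfig(seed=7, grid=(400.0, 2500.0, 10.0), n_samples=120)
    return generate(cfg)


@pytest.fixture(scope="session")
def default_dataset():
    """The generator's default study conditions (n=150, 2 nm grid)."""
    return generate(SyntheticConfig(seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
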