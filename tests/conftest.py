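import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from rloopedit.synthetic import SyntheticConfig, generate_all

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    """The default study conditions at a fixed seed."""
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def artifacts(default_config):
    """Full in-memory synthetic dataset generated once per session."""
    return generate_all(default_config)


@pytest.fixture(scope="session")
def small_artifacts():
    """A light-weight dataset for tests that only need structure, not power."""
    cfg = SyntheticConfig(
        seed=3,
        contigs=[("chr1", 150_000), ("chr2", 100_000)],
        n_rloops=40,
        n_rloop_mut=150,
        n_background_mut=60,
        n_clusters=4,
        n_a3b_peaks=30,
        n_dsb_peaks=80,
    )
    return cfg, generate_all(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
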