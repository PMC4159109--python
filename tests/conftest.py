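import numpy as np
import pytest

from cavmon.synth import SyntheticConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_config():
    """Reduced-scale study conditions: 0.05-s records at 4 MHz."""
    return SyntheticConfig.desk()


@pytest.fixture(scope="session")
def tiny_config():
    """Very short records for tests that only need the trial mechanics."""
    return SyntheticConfig.desk(record_duration=0.002)
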