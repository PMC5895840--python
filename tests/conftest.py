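import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def cfg():
    from pwlid.population import CellCycleConfig

    return CellCycleConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_system():
    """Piecewise-linear P/D system on N = 10, zero growth."""
    from pwlid.rates import pwl_system

    return pwl_system(10, [4.0, 5.0, 2.0], [1.0, 3.0, 6.0])
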