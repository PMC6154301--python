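import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_params():
    from cellpass import CellParams

    return CellParams()


@pytest.fixture
def single_source_field():
    """One source at the origin with table defaults (2D)."""
    from cellpass import ChemokineSource, SignalField

    return SignalField([ChemokineSource(np.array([0.0, 0.0]), 1.2e6)], D=3600.0, dim=2)
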