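import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_session():
    """One seeded synthetic session shared by read-only tests."""
    from audiophys import SessionConfig, synth_session
    return synth_session(SessionConfig(seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
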