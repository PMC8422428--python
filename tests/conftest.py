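import numpy as np
import pytest

from neurotelem.pipeline import SessionConfig, run_session
from neurotelem.synthgen import SynthesisConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def full_session_report():
    """One 16-channel, 30 s end-to-end session, shared across tests."""
    cfg = SessionConfig(
        synthesis=SynthesisConfig(n_channels=16, duration=30.0, seed=2024)
    )
    return run_session(cfg)
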