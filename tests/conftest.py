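import logging

import numpy as np
import pytest

import phasestates as ps

logging.getLogger("phasestates").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_session():
    """One tiny end-to-end session bundle shared across tests."""
    return ps.make_fixture("tiny", seed=1, std_pd=0.0, snr_db=40.0)


@pytest.fixture(scope="session")
def small_sources():
    """Six band-limited alpha sources, 20 s, for signal-level tests."""
    cfg = ps.BandLimitedConfig(n_sources=6, duration=20.0)
    return ps.generate_uncoupled_sources(cfg, np.random.default_rng(7))
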