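import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import bayeselicit as be

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def consensus_prior() -> be.NormalGammaBelief:
    """Consensus prior calibrated from the published summaries."""
    return be.calibrate_from_summaries()


@pytest.fixture(scope="session")
def panel() -> be.ExpertPanel:
    """The packaged 13-expert answer panel."""
    return be.packaged_panel()


@pytest.fixture(scope="session")
def trial_summaries() -> dict:
    return be.packaged_trial_summaries()


@pytest.fixture(scope="session")
def scenarios() -> list:
    return be.packaged_scenarios()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
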