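import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import photocif as pc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return pc.AgrpParams()


@pytest.fixture(scope="session")
def quiet_params():
    """All stochastic and artifact terms off; dynamics on."""
    return pc.AgrpParams(sigma_ou=0.0, noise_sd=0.0, motion_rate=0.0,
                         bleach=(0.0, 1.0, 0.0, 1.0))


@pytest.fixture()
def fed_quiet_protocol():
    """Fed, no food, no transfer: constant tonic drive."""
    return pc.Protocol(phase="homecage", state="fed", session_length=600.0,
                       context_entry_time=None, food_time=None)


@pytest.fixture(scope="session")
def training_session(params):
    """One default fasted training session rendered with artifacts."""
    proto = pc.Protocol.training(state="fasted", rng=np.random.default_rng(11))
    trace = pc.simulate_activity(params, proto, seed=11)
    session, truth = pc.render_photometry(trace, params, seed=11)
    return proto, session, truth
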