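import numpy as np
import pandas as pd
import pytest

from expviol.design import generate_session_exp1, session_to_frame
from expviol.simulate import ObserverParams, null_params, simulate_behavior_frame


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_session():
    return generate_session_exp1(seed=7)


@pytest.fixture(scope="session")
def exp1_frame(exp1_session):
    return session_to_frame(exp1_session)


def make_behavior_frame(n_trials, rng, observer_id=0, params=None, seed_frame=None):
    """A single-observer behavioral table over a fresh session design."""
    if seed_frame is None:
        n_sessions = int(np.ceil(n_trials / 384))
        frames = [session_to_frame(generate_session_exp1(rng=rng))
                  for _ in range(n_sessions)]
        frame = pd.concat(frames, ignore_index=True).iloc[:n_trials]
        frame = frame.assign(trial_id=np.arange(len(frame)))
    else:
        frame = seed_frame
    params = params or null_params()
    return simulate_behavior_frame(frame, params, rng, observer_id=observer_id)


@pytest.fixture(scope="session")
def large_null_behavior():
    """20,000 null-model trials from one observer (no condition effects)."""
    rng = np.random.default_rng(99)
    return make_behavior_frame(20000, rng, params=null_params(lapse_rate=0.0))
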