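import numpy as np
import pytest
from hypothesis import settings

from histddm.io import SessionTable, TrialRecord

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_trial(i, left=(), right=(), duration=0.5, choice="R", outcome="win",
               rt=None, violation=False, session_id="s0"):
    if violation:
        choice, outcome = "none", "none"
    return TrialRecord(
        trial_index=i, left_clicks=tuple(left), right_clicks=tuple(right),
        duration=duration, choice=choice, outcome=outcome, rt=rt,
        violation=violation, session_id=session_id,
    )


def random_click_trial(i, rng, rate_L=14.0, rate_R=26.0, duration=0.5, **kw):
    L = np.sort(rng.uniform(0, duration, rng.poisson(rate_L * duration)))
    R = np.sort(rng.uniform(0, duration, rng.poisson(rate_R * duration)))
    return make_trial(i, tuple(L), tuple(R), duration, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_session(rng):
    """10-trial session with mixed choices/outcomes and one violation."""
    trials = []
    specs = [("R", "win"), ("L", "loss"), ("R", "loss"), ("L", "win"), ("R", "win")]
    for i in range(10):
        if i == 5:
            trials.append(random_click_trial(i + 1, rng, violation=True))
        else:
            c, o = specs[i % len(specs)]
            trials.append(random_click_trial(i + 1, rng, choice=c, outcome=o))
    return SessionTable(tuple(trials))


@pytest.fixture(scope="session")
def click_fixture():
    """Deterministic 6-trial click fixture for solver cross-checks."""
    rng = np.random.default_rng(777)
    trials = []
    for i in range(6):
        rr, rl = [(26, 14), (22, 18), (14, 26)][i % 3]
        L = np.sort(rng.uniform(0, 0.5, rng.poisson(rl * 0.5)))
        R = np.sort(rng.uniform(0, 0.5, rng.poisson(rr * 0.5)))
        trials.append(make_trial(i + 1, tuple(L), tuple(R)))
    I = rng.uniform(-1.2, 1.2, 6)
    return trials, I
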