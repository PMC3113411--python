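import numpy as np
import pytest

from cortexloop.session import SessionConfig, SessionPlan, run_session
from cortexloop.simulate import SimConfig


@pytest.fixture(scope="session")
def small_session(tmp_path_factory):
    """One small but complete four-step session, shared by read-only tests.

    30 s baseline, 8 training trials, 6 closed-loop trials at strong
    modulation (d = 0.5) — big enough to exercise every phase transition,
    small enough to run once for the whole suite.
    """
    run_path = tmp_path_factory.mktemp("runs") / "small.h5"
    cfg = SessionConfig(sim=SimConfig(depth=0.5, seed=7))
    plan = SessionPlan(baseline_s=30.0, training_trials=8, control_trials=6)
    result = run_session(plan, cfg, run_path)
    return cfg, plan, result


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
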