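import numpy as np
import pytest

from autrel import AutomationSchedule, make_schedule, simulate_participant


@pytest.fixture(scope="session")
def exp2_schedule():
    return make_schedule(2, "start_high", seed=7)


@pytest.fixture(scope="session")
def delta_series(exp2_schedule):
    """A well-behaved delta-rule participant (160 contacts, sigma = 0.1)."""
    return simulate_participant(
        "delta", {"r0": 0.5, "alpha": 0.3, "sigma": 0.1}, exp2_schedule, seed=11
    )


@pytest.fixture(scope="session")
def short_schedule():
    """A small hand-built schedule (3 trials x 4 contacts) for fast fits."""
    trials = ((1, 1, 0, 1), (0, 1, 1, 1), (1, 0, 1, 0))
    return AutomationSchedule(experiment=1, condition="high", trials=trials, seed=0)
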