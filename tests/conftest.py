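import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from fedflux import fixtures as fx
from fedflux.fba import compute_stage_targets
from fedflux.loop import StageSchedule

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_network():
    return fx.make_toy_network()


@pytest.fixture(scope="session")
def stage_bounds():
    return fx.make_stage_bounds()


@pytest.fixture(scope="session")
def stage_targets(toy_network, stage_bounds):
    return compute_stage_targets(toy_network, stage_bounds)


@pytest.fixture(scope="session")
def params():
    return fx.make_nominal_params()


@pytest.fixture(scope="session")
def x0():
    return fx.make_initial_state()


@pytest.fixture(scope="session")
def schedule():
    return StageSchedule()


@pytest.fixture(scope="session")
def baseline_policy():
    return fx.make_baseline_policy()


@pytest.fixture(scope="session")
def feed_conc():
    return fx.feed_concentrations()


@pytest.fixture()
def no_feed_policy(feed_conc):
    from fedflux.twin import FeedPolicy

    return FeedPolicy(
        knots=np.array([0.0, 400.0]),
        F_in=np.zeros(2),
        F_out=np.zeros(2),
        C_feed_glc=np.zeros(2),
        C_feed_other=feed_conc,
    )
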