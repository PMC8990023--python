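import numpy as np
import pytest

import ncgamma as ng


@pytest.fixture(scope="session")
def default_train():
    """1 µs irradiation, default 200/11 ns micro-structure, 10k primaries."""
    return ng.build_pulse_train(1e3, 200.0, 11.0, 10_000, rng_seed=0)


@pytest.fixture(scope="session")
def b10_scenario_small():
    """B10 scenario at reduced scale for fast unit tests."""
    return ng.make_scenario("B10", total_ns=1e3, n_primaries=50_000, seed=3)


@pytest.fixture(scope="session")
def b10_events_small(b10_scenario_small):
    return ng.generate_events(b10_scenario_small)


@pytest.fixture(scope="session")
def gd_scenario_small():
    return ng.make_scenario("Gd157", total_ns=1e6, n_primaries=50_000, seed=5)


@pytest.fixture(scope="session")
def gd_events_small(gd_scenario_small):
    return ng.generate_events(gd_scenario_small)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
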