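import numpy as np
import pandas as pd
import pytest

from switchadjust import shipped_scenario, simulate_trial, apply_switching


@pytest.fixture(scope="session")
def scenario20():
    return shipped_scenario("scenario20")


@pytest.fixture(scope="session")
def scenario28():
    return shipped_scenario("scenario28")


@pytest.fixture(scope="session")
def trial_pair(scenario20):
    """One simulated trial (no-switching and switched variants)."""
    ns = simulate_trial(scenario20, seed=42)
    sw = apply_switching(ns, scenario20, seed=43)
    return ns, sw


@pytest.fixture(scope="session")
def big_trial_pair(scenario20):
    """A larger trial for estimator checks that need more switchers."""
    params = scenario20.with_(n_patients=3000)
    ns = simulate_trial(params, seed=7)
    sw = apply_switching(ns, params, seed=8)
    return ns, sw
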