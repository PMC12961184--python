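import numpy as np
import pytest

import curefollowup as cf


@pytest.fixture
def toy4():
    """Four subjects, last one censored: the hand-checkable alpha_n case."""
    return cf.SurvivalSample([1, 2, 3, 4], [1, 1, 1, 0])


@pytest.fixture
def all_events3():
    return cf.SurvivalSample([1, 2, 3], [1, 1, 1])


@pytest.fixture
def triweight():
    return cf.TRIWEIGHT


@pytest.fixture(scope="session")
def slope_table():
    return cf.default_slope_table()


@pytest.fixture(scope="session")
def setting1():
    """Setting-1 generator: Exp(1) uncured, uniform censoring with point
    mass 0.2 at tauG, uncured fraction 0.8."""
    return cf.make_setting(1, p=0.8, delta_g=0.2)


@pytest.fixture(scope="session")
def setting1_sample(setting1):
    tau_g = cf.uncured_quantile(setting1, 0.90)
    return cf.generate_sample(setting1, tau_g, n=500, seed=20251), tau_g


def random_sample(rng, n, p_event=0.6, tie_prob=0.0):
    """Small random right-censored sample, optionally with tied times."""
    times = rng.exponential(1.0, size=n).round(2 if tie_prob else 10)
    if tie_prob and n > 1:
        dup = rng.uniform(size=n) < tie_prob
        times[dup] = rng.choice(times, size=int(dup.sum()))
    events = (rng.uniform(size=n) < p_event).astype(int)
    return cf.SurvivalSample(times=times, events=events)
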