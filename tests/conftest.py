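import numpy as np
import pandas as pd
import pytest

from cohortsample.cohort_model import Cohort


def make_cohort(times, events, **covariates) -> Cohort:
    n = len(times)
    df = pd.DataFrame({"id": [f"p{i}" for i in range(n)],
                       "time": times, "event": events})
    for name, values in covariates.items():
        df[name] = values
    return Cohort(df)


@pytest.fixture
def toy5():
    """Five subjects, cases at t=1 and t=3 — the worked NCC example."""
    return make_cohort([1, 2, 3, 4, 5], [1, 0, 1, 0, 0])


@pytest.fixture
def toy_egs():
    """Five subjects for the extreme-group worked example."""
    return make_cohort([0.5, 1.5, 3, 6, 7], [1, 1, 1, 0, 1])


@pytest.fixture
def toy10():
    """Ten subjects, four events, a binary covariate."""
    rngless_x = [1, 0, 1, 0, 0, 1, 0, 1, 0, 0]
    return make_cohort(np.arange(1, 11) / 2.0,
                       [1, 1, 0, 1, 0, 0, 1, 0, 0, 0], x=rngless_x)


@pytest.fixture(scope="session")
def two_group_cohort():
    """n=4000 exponential two-group cohort, true log HR = -0.7."""
    rng = np.random.default_rng(314)
    n = 4000
    x = (rng.random(n) < 0.5).astype(int)
    t = rng.exponential(scale=1.0, size=n) / np.exp(-0.7 * x)
    c = rng.uniform(0, 4.0, size=n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    return make_cohort(np.maximum(time, 1e-9), event, x=x)
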