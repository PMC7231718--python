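import numpy as np
import pytest

from gbscure import synthetic


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-subject synthetic cohort shared by fast model tests."""
    df, truth = synthetic.generate_cohort(synthetic.default_config(seed=7, n=400))
    return df, truth


@pytest.fixture()
def toy_survival():
    """Hand-checkable 5-subject dataset: events at 1, 2, 4; censored at 3, 5."""
    times = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    events = np.array([1, 1, 0, 1, 0])
    return times, events
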