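import numpy as np
import pytest
from hypothesis import settings

import gravityprior as gp

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_design():
    """One repetition per condition (136 rows)."""
    return gp.build_design(1, 1)


@pytest.fixture(scope="session")
def midpoint_trials(small_design):
    """Deterministic trial table at occlusion-window midpoints."""
    return gp.trial_table(small_design, fractions="midpoint")


@pytest.fixture(scope="session")
def positive_trials(midpoint_trials):
    return midpoint_trials[
        (midpoint_trials["gravity_multiple"] > 0) & (midpoint_trials["block"] < 4)
    ].reset_index(drop=True)


@pytest.fixture(scope="session")
def table1():
    return gp.table1_fixture()
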