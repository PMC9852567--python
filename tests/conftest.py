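import numpy as np
import pytest

from urivar import SimParams, default_panel, simulate_cohort


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def small_cohort(panel):
    """A small mixed cohort shared by read-only tests."""
    params = SimParams(
        seed=11,
        n_non_bc=60,
        n_bc=30,
        n_surveillance_no_recur=40,
        n_surveillance_recur=10,
        n_surveillance_pre_recur=6,
    )
    metas, counts, truth = simulate_cohort(panel, params)
    return params, metas, counts, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
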