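import numpy as np
import pytest

from migconn import CohortSpec, generate_node_timeseries_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A small null cohort reused by read-only tests."""
    spec = CohortSpec(n_em=8, n_cm=6, n_volumes=80, n_nodes=5, seed=7)
    return generate_node_timeseries_cohort(spec)
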