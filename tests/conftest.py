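import numpy as np
import pandas as pd
import pytest

from tmescape.simulate import (
    CohortConfig,
    make_signature,
    simulate_cohort,
    simulate_mixtures,
    write_bundle,
)


@pytest.fixture(scope="session")
def signature():
    return make_signature(220, 22, 10, 5.0, seed=1)


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-sample three-group cohort shared by read-only tests."""
    cfg = CohortConfig(group_sizes={"A": 20, "B": 20, "C": 20})
    return simulate_cohort(cfg, seed=11)


@pytest.fixture(scope="session")
def cohort_dir(small_cohort, tmp_path_factory):
    d = tmp_path_factory.mktemp("cohort")
    write_bundle(small_cohort, d)
    return d


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
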