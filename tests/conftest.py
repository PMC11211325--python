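import numpy as np
import pytest

from fcsubtype.cohort import CohortSpec, simulate_cohort
from fcsubtype.io import default_parcellation
from fcsubtype.network_fc import NetworkPartition


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240627)


@pytest.fixture(scope="session")
def small_partition():
    # 14 regions, 7 networks of 2 - the smallest valid partition
    return NetworkPartition.from_parcellation(default_parcellation(14))


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_regions=28, n_per_group={"subtype_I": 8, "subtype_II": 5, "CN": 6},
                      seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """Matrix-mode cohort: fast, used by tests that don't need time series."""
    return simulate_cohort(small_spec, mode="matrix")


@pytest.fixture(scope="session")
def default_cohort():
    """One time-series cohort at the default desk scale (60 regions)."""
    return simulate_cohort(CohortSpec(seed=3), mode="timeseries")
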