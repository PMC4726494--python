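import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from cobitis.karyotype import load_reference_table
from cobitis.cohort import load_cohort


@pytest.fixture(scope="session")
def ref_table():
    return load_reference_table()


@pytest.fixture(scope="session")
def cohort_records():
    return load_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20160125)
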