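import pandas as pd
import pytest

from haeclaims.fixtures import generate_fixture
from haeclaims.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def sim_small():
    """A 300-patient simulated dataset shared by read-only tests."""
    return generate_cohort(SimConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def epi_fixture():
    return generate_fixture("F-EPI")


@pytest.fixture(scope="session")
def tab4_fixture():
    return generate_fixture("F-TAB4")


@pytest.fixture(scope="session")
def cvad_fixture():
    return generate_fixture("F-CVAD")


@pytest.fixture(scope="session")
def cohort_fixture():
    return generate_fixture("F-COHORT")


@pytest.fixture(scope="session")
def all_fixture():
    return generate_fixture("F-ALL")


def make_fills(days, iu=1000.0, supply=4, pid="p1", product="CINRYZE"):
    """Build segment_runs-style fill tuples from day offsets."""
    base = pd.Timestamp("2010-01-01")
    return [(pid, product, base + pd.Timedelta(days=int(d)), iu, supply)
            for d in days]
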