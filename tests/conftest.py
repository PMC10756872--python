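import pytest

from famvar.fixture import paper_fixture
from famvar.synthetic_cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def bundle():
    """The in-study reference cohort with its companion resources."""
    return paper_fixture()


@pytest.fixture(scope="session")
def fixture_cohort(bundle):
    return bundle.cohort


@pytest.fixture(scope="session")
def sim():
    """One deterministic simulated cohort at the default study shape."""
    return generate_cohort(CohortSpec(seed=11))


KEYS = {
    "MAST4": "5:65892764:C:CGCT",
    "ITGA6": "2:173337540:G:GA",
    "PITX2": "4:111542154:G:A",
    "CACNA1S": "1:201016296:G:A",
    "CDON": "11:125871715:G:A",
}
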