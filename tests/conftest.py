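import pytest
from hypothesis import settings

# reproducible property tests regardless of how pytest is invoked
settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from domevol import build_cohort_db
from domevol.synthetic import ferm_c_fixture


@pytest.fixture(scope="session")
def ferm_cohort():
    return ferm_c_fixture()


@pytest.fixture()
def ferm_db(ferm_cohort):
    db = build_cohort_db(ferm_cohort)
    yield db
    db.close()
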