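import pytest
from hypothesis import settings

from monotriage import ScoreConfig, paper_fixture

settings.register_profile("ci", derandomize=True, max_examples=100)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 196-patient reference cohort."""
    return paper_fixture()


@pytest.fixture(scope="session")
def cfg():
    return ScoreConfig()
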