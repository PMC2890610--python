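import pytest
from hypothesis import settings

from isomaxent import load_study_tables

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_tables():
    return load_study_tables()


@pytest.fixture(scope="session")
def binding(study_tables):
    return study_tables[0]


@pytest.fixture(scope="session")
def cytotox(study_tables):
    return study_tables[1]


@pytest.fixture(scope="session")
def expression(study_tables):
    return study_tables[2]
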