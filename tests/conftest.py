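import pytest

from heartcoach import (
    DEFAULT_CONFIG,
    default_catalog,
    default_item_bank,
    fixture_study_cohort,
    replay_events,
)


@pytest.fixture(scope="session")
def bank():
    return default_item_bank()


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def config():
    return DEFAULT_CONFIG


@pytest.fixture(scope="session")
def fixture_events(bank):
    return fixture_study_cohort(bank)


@pytest.fixture(scope="session")
def fixture_replay(fixture_events):
    return replay_events(fixture_events)
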