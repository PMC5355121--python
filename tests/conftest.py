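import pytest

from thiometa import table1_fixture
from thiometa.meta import log_odds_ratio
from thiometa.models import ModelKind, contrasts_for


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture(scope="session")
def allele_tables(table1):
    return contrasts_for(table1, ModelKind.ALLELE)


@pytest.fixture(scope="session")
def allele_effects(allele_tables):
    return [log_odds_ratio(t) for t in allele_tables]
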