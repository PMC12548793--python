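import pytest

from abx_carbon.calculators import load_synonyms
from abx_carbon.fixtures import load_fixture
from abx_carbon.reference_data import (
    DisposalScenario,
    packaged_data_path,
    packaged_emission_factors,
    packaged_equivalency_factors,
)


@pytest.fixture(scope="session")
def factor_table():
    return packaged_emission_factors()


@pytest.fixture(scope="session")
def equivalencies():
    return packaged_equivalency_factors()


@pytest.fixture()
def scenario():
    return DisposalScenario()


@pytest.fixture(scope="session")
def synonyms():
    return load_synonyms()


@pytest.fixture(scope="session")
def worked_example_dir():
    return packaged_data_path("worked_example")


@pytest.fixture(scope="session")
def worked_bundle(worked_example_dir, factor_table):
    return load_fixture(worked_example_dir, factor_table=factor_table)
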