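import pytest

from polybigsmiles.validation_suite import load_fixtures


@pytest.fixture(scope="session")
def all_fixture_records():
    return load_fixtures()


@pytest.fixture(scope="session")
def table1_records(all_fixture_records):
    return [r for r in all_fixture_records if r.provenance == "table1"]


@pytest.fixture(scope="session")
def fixture_units(all_fixture_records):
    """Normalized two-point reference units from the packaged fixtures."""
    return [r.normalized_reference for r in all_fixture_records]
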