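import pytest

from surrogateval import build_analysis_set, fixture_table, to_effects


@pytest.fixture(scope="session")
def records():
    return fixture_table()


def _effects_for(records, set_name):
    aset = build_analysis_set(records, set_name)
    return to_effects(aset.select(records))


@pytest.fixture(scope="session")
def primary_effects(records):
    return _effects_for(records, "primary")


@pytest.fixture(scope="session")
def all_effects(records):
    return _effects_for(records, "sensitivity_1")


@pytest.fixture(scope="session")
def reduced_effects(records):
    return _effects_for(records, "sensitivity_2")
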