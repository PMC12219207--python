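import pytest

from tiqspr import fixtures


@pytest.fixture(scope="session")
def property_table():
    return fixtures.load_property_table()


@pytest.fixture(scope="session")
def index_table():
    return fixtures.load_index_table()


@pytest.fixture(scope="session")
def model_specs():
    return fixtures.load_model_specs()


@pytest.fixture(scope="session")
def diclofenac_graph():
    return fixtures.diclofenac_graph()


@pytest.fixture(scope="session")
def diclofenac_partition():
    return fixtures.diclofenac_partition()


#: the published Diclofenac index values (3-decimal table precision)
DICLOFENAC_PRINTED = {
    "M1": 94, "M2": 107, "H": 8.7, "HM": 452, "F": 238, "ABC": 14.458,
    "R": 9.075, "SC": 9.302, "GA": 19.302, "SO": 68.363, "N": 43.237,
}
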