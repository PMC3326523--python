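import pytest

from bromokit.histones import default_collection


@pytest.fixture(scope="session")
def histones():
    return default_collection()


@pytest.fixture(scope="session")
def h3(histones):
    return histones["H3"]


@pytest.fixture(scope="session")
def h4(histones):
    return histones["H4"]
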