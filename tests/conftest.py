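import pytest

from sdpricing import SimConfig, build_japan_model

STOCK = "new drug pricing decision evaluation"
FLOW = "new drug pricing decision variation"


@pytest.fixture(scope="session")
def japan():
    return build_japan_model()


@pytest.fixture()
def config():
    return SimConfig()
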