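import pytest

from ampliscope.insilico_pcr import builtin_panel
from ampliscope.synthetic_data import make_reference_world


@pytest.fixture(scope="session")
def panel():
    return builtin_panel()


@pytest.fixture(scope="session")
def world():
    """One default 12-species synthetic world shared across tests."""
    return make_reference_world(seed=1)
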