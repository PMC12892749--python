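import numpy as np
import pytest

from eznetsi.synthetic_data import default_head, make_lead_field


@pytest.fixture(scope="session")
def head16():
    return default_head(16)


@pytest.fixture(scope="session")
def lf16(head16):
    return make_lead_field(head16)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
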