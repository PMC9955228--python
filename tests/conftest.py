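import numpy as np
import pytest

from cranioangle import GeometryConfig, template_head


@pytest.fixture
def template():
    return template_head()


@pytest.fixture
def cfg():
    return GeometryConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
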