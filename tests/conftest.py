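import numpy as np
import pytest

import mtvaper as mv


@pytest.fixture(scope="session")
def model():
    return mv.default_model()


@pytest.fixture(scope="session")
def protocol():
    return mv.AcquisitionProtocol()


@pytest.fixture(scope="session")
def dante_train():
    return mv.default_dante_train()


@pytest.fixture(scope="session")
def mt_train():
    return mv.default_mt_train()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
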