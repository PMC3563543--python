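import numpy as np
import pytest

from capsidyn.geometry import build_blueprint


@pytest.fixture(scope="session")
def bp_t1():
    return build_blueprint(1, "hierarchical")


@pytest.fixture(scope="session")
def bp_t1_direct():
    return build_blueprint(1, "direct")


@pytest.fixture(scope="session")
def bp_t3():
    return build_blueprint(3, "hierarchical")


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
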