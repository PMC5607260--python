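import numpy as np
import pytest

from ligandtree.model import build_model
from ligandtree.network import CellLineContext, ModelSpec
from ligandtree.params import KineticParameterSet


@pytest.fixture(scope="session")
def full_model():
    spec = ModelSpec.full()
    return build_model(spec, KineticParameterSet.defaults(spec))


@pytest.fixture(scope="session")
def small_model():
    """Scaled-down two-receptor network for fast numerical tests."""
    spec = ModelSpec.custom(("EGFR", "HER2"), heterodimers=(("EGFR", "HER2"),))
    return build_model(spec, KineticParameterSet.defaults(spec))


@pytest.fixture
def context():
    return CellLineContext(
        "TEST-LINE",
        {"EGFR": 2e5, "HER2": 1e5, "ErbB3": 3e4, "Met": 5e4, "IGF1R": 8e4},
    )


@pytest.fixture
def small_context():
    return CellLineContext("SMALL-LINE", {"EGFR": 2e5, "HER2": 1e5})


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)
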