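import pytest

from halopbpk.compounds import haloperidol_model, reduced_haloperidol_model
from halopbpk.physiology import build_reference_individual


@pytest.fixture(scope="session")
def hal():
    return haloperidol_model()


@pytest.fixture(scope="session")
def rhal():
    return reduced_haloperidol_model()


@pytest.fixture(scope="session")
def reference_individual():
    return build_reference_individual()
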