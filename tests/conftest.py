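import pytest
from hypothesis import settings

from aakin.io import load_builtin_enzyme, make_mm_oracle_fixture

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cys_model():
    return load_builtin_enzyme("cysRS")


@pytest.fixture(scope="session")
def his_model():
    return load_builtin_enzyme("hisRS")


@pytest.fixture(scope="session")
def mm_oracle():
    """2-state charging mechanism with exact MM kinetics (kcat 10, Km 5)."""
    return make_mm_oracle_fixture(10.0, 5.0)
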