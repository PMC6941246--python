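import pytest

from withinhost.models import (
    make_basic_bacteria_model,
    make_saturated_immunity_model,
    resolve_parameters,
)


@pytest.fixture(scope="session")
def basic():
    return make_basic_bacteria_model()


@pytest.fixture(scope="session")
def saturated():
    return make_saturated_immunity_model()


@pytest.fixture
def basic_defaults(basic):
    return resolve_parameters(basic)


@pytest.fixture
def saturated_defaults(saturated):
    return resolve_parameters(saturated)
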