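import pytest

from screencea.synthetic import SyntheticSpec, generate_parameter_set, toy_fixture


@pytest.fixture(scope="session")
def urban_params():
    return generate_parameter_set(SyntheticSpec(seed=11, setting="urban"))


@pytest.fixture(scope="session")
def rural_params():
    return generate_parameter_set(SyntheticSpec(seed=11, setting="rural"))


@pytest.fixture()
def two_state():
    return toy_fixture("two_state")


@pytest.fixture()
def four_state():
    return toy_fixture("four_state_chain")
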