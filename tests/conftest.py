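import pytest

from prucea import default_parameters, run_base_case


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def base_result(params):
    return run_base_case(params)
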