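import pytest

from pukinetics import DEFAULT_GRID, default_parameter_set


@pytest.fixture
def params():
    return default_parameter_set()


@pytest.fixture
def grid():
    return DEFAULT_GRID
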