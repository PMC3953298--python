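import numpy as np
import pytest

from gnrherk import ParameterSet, resting_state


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def rest(params) -> np.ndarray:
    return resting_state(params)
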