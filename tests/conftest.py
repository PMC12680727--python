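import numpy as np
import pytest

from sersmix import WavenumberAxis, default_axis, default_library


@pytest.fixture(scope="session")
def axis():
    return default_axis()


@pytest.fixture(scope="session")
def library(axis):
    return default_library(axis)


@pytest.fixture
def small_axis():
    return WavenumberAxis(np.arange(60, dtype=float))
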