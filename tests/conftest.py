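import numpy as np
import pytest

from prawnvision import DEFAULT_GRID, Spectrum, goby, pollack


@pytest.fixture(scope="session")
def pollack_system():
    return pollack()


@pytest.fixture(scope="session")
def goby_system():
    return goby()


@pytest.fixture
def flat_spectrum():
    def make(value: float, name: str = "flat") -> Spectrum:
        return Spectrum(DEFAULT_GRID, np.full(DEFAULT_GRID.size, value), name=name)

    return make
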