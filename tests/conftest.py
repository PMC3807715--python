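import numpy as np
import pytest

from neuroband.spectral import analysis_grid, PowerSpectrum


@pytest.fixture
def grid():
    return analysis_grid()


@pytest.fixture
def flat_spectrum(grid):
    return PowerSpectrum(grid, np.ones_like(grid), n_epochs=1)


def make_spectrum(power, n_epochs=1):
    grid = analysis_grid()
    power = np.asarray(power, dtype=float)
    assert power.shape == grid.shape
    return PowerSpectrum(grid, power, n_epochs=n_epochs)


@pytest.fixture
def spectrum_factory():
    return make_spectrum
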