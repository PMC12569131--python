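import numpy as np
import pytest

from mosqnir import simulate as sim


@pytest.fixture
def wing_grid():
    return sim.WING_GRID_NM


@pytest.fixture
def body_grid():
    return sim.BODY_GRID_NM


@pytest.fixture
def noiseless_wing():
    """Noise-free 288-band wing spectrum at a mid-range thickness."""
    return sim.gen_wing_spectrum(250.0, a=0.9, b=0.1, snr=1e12, seed=0)


@pytest.fixture
def noiseless_body():
    """Noise-free polarized body spectra at the default medians."""
    return sim.gen_body_spectra(snr_copol=1e12, snr_depol=1e12, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
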