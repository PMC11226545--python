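import numpy as np
import pytest

from oscflux import AperiodicSpec, gen_aperiodic_noise, morlet_tfr, freq_grid

FS = 250.0


@pytest.fixture(scope="session")
def freqs():
    return freq_grid()


@pytest.fixture(scope="session")
def background_spec():
    return AperiodicSpec(offset=2.0, knee=0.0, exponent=1.5, fs=FS, duration=2.0)


@pytest.fixture(scope="session")
def long_background():
    """60 s of 1/f^1.5 background at 250 Hz (shared across spectral tests)."""
    spec = AperiodicSpec(offset=2.0, knee=0.0, exponent=1.5, fs=FS, duration=60.0)
    return spec, gen_aperiodic_noise(spec, seed=11)


@pytest.fixture(scope="session")
def long_background_tfr(long_background, freqs):
    spec, series = long_background
    return morlet_tfr(series, FS, freqs)
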