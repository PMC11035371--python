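import numpy as np
import pytest

from ictalab import synth
from ictalab.signal_io import Recording


@pytest.fixture(scope="session")
def pink_recording():
    """10-min single-channel 1/f background, 50 Hz line, fixed seed."""
    return synth.gen_background(1000.0, 600.0, 1, pink_exponent=1.0,
                                line_amp=5.0, seed=42)


@pytest.fixture(scope="session")
def clean_recording():
    """10-min line-free background for detector tests."""
    return synth.gen_background(1000.0, 600.0, 1, pink_exponent=1.0,
                                line_amp=0.0, seed=7)


@pytest.fixture()
def sine_recording():
    fs = 1000.0
    t = np.arange(int(10 * fs)) / fs
    x = 20.0 * np.sin(2 * np.pi * 10.0 * t)
    return Recording(x[None, :], fs, ["ch0"])
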