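import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def ripple_patch(rate_hz, scale_cpo, n_t=50, n_f=60, frame_ms=5.0, ch_per_octave=10, direction="down"):
    """Drifting-ripple STRF patch cos(2 pi (rate t +- scale x)) on the analysis grid."""
    t = np.arange(n_t)[:, None] * frame_ms / 1000.0
    x = np.arange(n_f)[None, :] / ch_per_octave
    sgn = 1.0 if direction == "down" else -1.0
    return np.cos(2 * np.pi * (rate_hz * t + sgn * scale_cpo * x))


@pytest.fixture
def make_ripple_patch():
    return ripple_patch
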