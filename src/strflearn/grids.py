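"""Shared tonotopic / modulation axis definitions.

The tonotopic axis spans six octaves above 62.5 Hz with ten logarithmically
equally spaced channels per octave (60 channels, 62.5 Hz <= f_c < 4000 Hz).
Spectro-temporal patches are sampled every 5 ms and span 250 ms, so the
modulation (Fourier) axes have a rate step of 4 Hz and a scale step of
1/6 cyc/oct.
"""

from __future__ import annotations

import numpy as np

F_LOW_HZ = 62.5
N_OCTAVES = 6
CH_PER_OCTAVE = 10
N_CHANNELS = N_OCTAVES * CH_PER_OCTAVE
FRAME_MS = 5.0
SAMPLE_RATE_HZ = 8000
PATCH_FRAMES = 50  # 250 ms at 5 ms/frame
PATCH_SHAPE = (PATCH_FRAMES, N_CHANNELS)


def center_frequencies(
    n_octaves: int = N_OCTAVES,
    ch_per_octave: int = CH_PER_OCTAVE,
    f_low_hz: float = F_LOW_HZ,
) -> np.ndarray:
    """Center frequencies f_c = f_low * 2**(c / ch_per_octave), c = 0..n-1."""
    c = np.arange(n_octaves * ch_per_octave)
    return f_low_hz * 2.0 ** (c / ch_per_octave)


def channel_octaves(n_channels: int = N_CHANNELS, ch_per_octave: int = CH_PER_OCTAVE) -> np.ndarray:
    """Channel positions in octaves above the lowest channel."""
    return np.arange(n_channels) / ch_per_octave
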