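"""Simplified peripheral auditory model.

Maps a mono waveform to an *auditory spectrogram*: a time x tonotopic-channel
energy matrix with 5-ms frames and 60 constant-Q channels spanning six
octaves (62.5-4000 Hz, ten channels per octave).  The stages are:

1. constant-Q bandpass filterbank (2nd-order Butterworth, band edges at the
   half-channel spacing so adjacent filters cross near -3 dB),
2. half-wave rectification (inner hair cell transduction),
3. first difference toward higher channels + rectification (lateral
   inhibitory sharpening in the cochlear nucleus),
4. 5-ms window integration (loss of phase locking in the midbrain).

All stages are linear or positively homogeneous, so doubling the input
amplitude doubles the output; an optional cube-root compression is off by
default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .grids import CH_PER_OCTAVE, F_LOW_HZ, FRAME_MS, N_OCTAVES, SAMPLE_RATE_HZ, center_frequencies
from .stimgen import Waveform

__all__ = ["AuditorySpectrogram", "Filterbank", "design_filterbank", "compute_spectrogram"]


@dataclass
class AuditorySpectrogram:
    """Frames x channels non-negative energy matrix on the tonotopic axis."""

    values: np.ndarray
    center_freqs_hz: np.ndarray
    frame_ms: float = FRAME_MS

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.center_freqs_hz = np.asarray(self.center_freqs_hz, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != self.center_freqs_hz.size:
            raise ValueError("values must be frames x channels matching center_freqs_hz")
        if np.any(np.diff(self.center_freqs_hz) <= 0):
            raise ValueError("center frequencies must be strictly ascending")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


@dataclass
class Filterbank:
    sos: list
    center_freqs_hz: np.ndarray
    rate_hz: int


def design_filterbank(
    n_octaves: int = N_OCTAVES,
    ch_per_octave: int = CH_PER_OCTAVE,
    f_low_hz: float = F_LOW_HZ,
    rate_hz: int = SAMPLE_RATE_HZ,
    order: int = 2,
) -> Filterbank:
    """Constant-Q bandpass filterbank centered at f_c = f_low * 2**(c/ch_per_octave).

    Band edges sit at the geometric half-channel spacing f_c * 2**(+-1/(2*cpo)),
    so adjacent filter magnitude responses cross near their -3 dB points.
    """
    if f_low_hz * 2.0**n_octaves > rate_hz / 2:
        raise ValueError("top octave exceeds the Nyquist frequency")
    fc = center_frequencies(n_octaves, ch_per_octave, f_low_hz)
    half = 2.0 ** (1.0 / (2 * ch_per_octave))
    sos = [
        signal.butter(order, [f / half, min(f * half, rate_hz / 2 * 0.999)], btype="bandpass", fs=rate_hz, output="sos")
        for f in fc
    ]
    return Filterbank(sos=sos, center_freqs_hz=fc, rate_hz=rate_hz)


def compute_spectrogram(
    wav: Waveform,
    filterbank: Filterbank | None = None,
    compress: bool = False,
) -> AuditorySpectrogram:
    """Waveform -> auditory spectrogram (see module docstring for stages)."""
    if len(wav.samples) == 0:
        raise ValueError("empty waveform")
    fb = filterbank or design_filterbank(rate_hz=wav.rate_hz)
    if fb.rate_hz != wav.rate_hz:
        raise ValueError("filterbank sample rate does not match waveform")

    frame_len = int(round(FRAME_MS / 1000 * wav.rate_hz))
    n_frames = len(wav.samples) // frame_len
    if n_frames < 1:
        raise ValueError("waveform shorter than one 5-ms frame")

    n = n_frames * frame_len
    x = wav.samples[:n].astype(np.float32)
    n_ch = fb.center_freqs_hz.size
    rect = np.empty((n, n_ch), dtype=np.float32)
    for c in range(n_ch):
        y = signal.sosfilt(fb.sos[c], x)
        rect[:, c] = np.maximum(y, 0.0)

    # Lateral inhibition: first difference toward higher channels, rectified.
    lin = np.empty_like(rect)
    lin[:, 0] = rect[:, 0]
    lin[:, 1:] = rect[:, 1:] - rect[:, :-1]
    np.maximum(lin, 0.0, out=lin)

    frames = lin.reshape(n_frames, frame_len, n_ch).mean(axis=1).astype(np.float64)
    if compress:
        frames = np.cbrt(frames)
    return AuditorySpectrogram(values=frames, center_freqs_hz=fb.center_freqs_hz)
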