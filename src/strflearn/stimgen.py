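"""Synthetic acoustic stimuli with controlled spectro-temporal modulation content.

Natural sound ensembles (speech, animal vocalizations, ambient noise) share a
characteristic joint modulation spectrum: energy concentrated at slow temporal
rates (below ~20 Hz) and low spectral scales (below ~1 cyc/oct).  The
generators here synthesize surrogate stimuli whose modulation statistics are
controlled explicitly — drifting spectro-temporal ripples, harmonic
vocalization-like calls, and low-pass modulated noise — and mix them into a
standardized segment ensemble.  A separate latent-factor generator plants a
known "slow" subspace into abstract patch data, serving as a recovery fixture
for the temporal-slowness learning objective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .grids import (
    CH_PER_OCTAVE,
    N_CHANNELS,
    SAMPLE_RATE_HZ,
    center_frequencies,
    channel_octaves,
)

__all__ = [
    "Waveform",
    "StimulusRecipe",
    "gen_moving_ripple",
    "gen_harmonic_call",
    "gen_modulated_noise",
    "gen_stimulus_ensemble",
    "gen_slow_latent_patches",
    "gen_sparse_latent_patches",
]


@dataclass
class Waveform:
    """A mono audio signal.

    Parameters
    ----------
    samples : ndarray
        Real-valued samples, arbitrary amplitude units.
    rate_hz : int
        Sampling rate in samples/second (default 8000).
    """

    samples: np.ndarray
    rate_hz: int = SAMPLE_RATE_HZ

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("waveform must be mono (1-D)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    def write_wav(self, path, dtype: str = "float32") -> None:
        if dtype == "float32":
            wavfile.write(path, self.rate_hz, self.samples.astype(np.float32))
        elif dtype == "int16":
            peak = np.max(np.abs(self.samples)) or 1.0
            scaled = np.clip(self.samples / peak, -1, 1) * 32767
            wavfile.write(path, self.rate_hz, scaled.astype(np.int16))
        else:
            raise ValueError(f"unsupported WAV dtype {dtype!r}")

    @classmethod
    def read_wav(cls, path) -> "Waveform":
        rate, data = wavfile.read(path)
        is_int = np.issubdtype(data.dtype, np.integer)
        data = np.asarray(data, dtype=np.float64)
        if data.ndim > 1:
            data = data.mean(axis=1)
        if is_int:
            data = data / 32768.0
        return cls(samples=data, rate_hz=int(rate))


@dataclass
class StimulusRecipe:
    """Composition of a synthetic stimulus ensemble.

    Segments of ``segment_duration_s`` are drawn from three surrogate sound
    classes (speech-like harmonic calls, vocalization-like ripple mixtures,
    ambient-like modulated noise), standardized to zero mean / unit variance,
    raised-cosine tapered, and concatenated in seeded random order.
    """

    total_duration_s: float = 180.0
    segment_duration_s: float = 3.0
    class_fractions: tuple = (0.5, 0.25, 0.25)
    taper_ms: float = 50.0
    seed: int = 0

    def __post_init__(self):
        fr = np.asarray(self.class_fractions, dtype=float)
        if fr.size != 3 or np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
            raise ValueError("class_fractions must be 3 non-negative values summing to 1")
        if self.total_duration_s < self.segment_duration_s:
            raise ValueError("total_duration_s must cover at least one segment")
        if self.segment_duration_s <= 0:
            raise ValueError("segment_duration_s must be positive")


def _rms_normalize(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def gen_moving_ripple(
    rate_hz: float,
    scale_cpo: float,
    duration_s: float,
    direction: str = "down",
    seed: int = 0,
    depth: float = 0.9,
    fs: int = SAMPLE_RATE_HZ,
) -> Waveform:
    """Drifting spectro-temporal ripple.

    A sum of 60 log-spaced tone carriers (matching the analysis channels,
    62.5–4000 Hz) whose amplitudes follow a sinusoidal envelope drifting at
    ``rate_hz`` (temporal modulation) and ``scale_cpo`` (spectral modulation,
    cycles/octave).  ``direction='down'`` sweeps envelope crests from high to
    low frequency.  The output is RMS-normalized.
    """
    if not (0 <= rate_hz < 100):
        raise ValueError("rate_hz must satisfy 0 <= rate_hz < 100")
    if not (0 <= scale_cpo <= 5):
        raise ValueError("scale_cpo must lie in [0, 5]")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    fc = center_frequencies()
    x = channel_octaves()
    phases = rng.uniform(0, 2 * np.pi, size=fc.size)
    sgn = 1.0 if direction == "down" else -1.0

    sig = np.zeros(n)
    # Per-channel accumulation keeps peak memory at one (n,) buffer per carrier.
    for c in range(fc.size):
        env = 1.0 + depth * np.sin(2 * np.pi * (rate_hz * t + sgn * scale_cpo * x[c]))
        sig += env * np.sin(2 * np.pi * fc[c] * t + phases[c])
    return Waveform(_rms_normalize(sig), fs)


def gen_harmonic_call(
    f0_contour,
    formant_centers,
    am_rate_hz: float,
    duration_s: float,
    seed: int = 0,
    fs: int = SAMPLE_RATE_HZ,
) -> Waveform:
    """Harmonic stack with pitch contour, formant envelope, and amplitude modulation.

    ``f0_contour`` is a sequence of fundamental-frequency values (Hz)
    interpolated linearly across the call; harmonics are shaped by Gaussian
    formant resonances (on a log-frequency axis) centered at
    ``formant_centers`` and the whole call is amplitude-modulated at
    ``am_rate_hz`` (0 disables AM).
    """
    f0_contour = np.atleast_1d(np.asarray(f0_contour, dtype=float))
    if f0_contour.size == 0:
        raise ValueError("f0_contour must be non-empty")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if np.any(f0_contour < 62.5) or np.any(f0_contour > 4000):
        raise ValueError("f0 values must lie within 62.5-4000 Hz")
    formant_centers = np.atleast_1d(np.asarray(formant_centers, dtype=float))
    if formant_centers.size and (formant_centers.min() < 62.5 or formant_centers.max() > 4000):
        raise ValueError("formant centers must lie within 62.5-4000 Hz")
    if am_rate_hz < 0:
        raise ValueError("am_rate_hz must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if f0_contour.size == 1:
        f0 = np.full(n, f0_contour[0])
    else:
        f0 = np.interp(t, np.linspace(0, duration_s, f0_contour.size), f0_contour)
    phase0 = 2 * np.pi * np.cumsum(f0) / fs

    n_harm = max(1, int(4000 // f0.max()))
    sig = np.zeros(n)
    for k in range(1, n_harm + 1):
        fk = k * f0
        valid = fk < fs / 2
        if not valid.any():
            break
        if formant_centers.size:
            logf = np.log2(np.clip(fk, 1e-6, None))
            amp = np.zeros(n)
            for fcen in formant_centers:
                amp += np.exp(-0.5 * ((logf - np.log2(fcen)) / 0.5) ** 2)
            amp += 0.05
        else:
            amp = np.full(n, 1.0 / k)
        sig += np.where(valid, amp * np.sin(k * phase0 + rng.uniform(0, 2 * np.pi)), 0.0)

    if am_rate_hz > 0:
        sig *= 0.5 * (1.0 + 0.9 * np.sin(2 * np.pi * am_rate_hz * t + rng.uniform(0, 2 * np.pi)))
    return Waveform(_rms_normalize(sig), fs)


def gen_modulated_noise(
    rate_cutoff_hz: float,
    scale_cutoff_cpo: float,
    duration_s: float,
    seed: int = 0,
    fs: int = SAMPLE_RATE_HZ,
    depth: float = 0.8,
) -> Waveform:
    """Noise-like texture whose modulation spectrum is low-pass in rate and scale.

    A random spectrogram envelope on the (5-ms frame, 60-channel) grid is
    low-pass filtered in 2D below the stated cutoffs and used to
    amplitude-modulate narrowband carriers at the channel center frequencies.
    """
    if rate_cutoff_hz <= 0 or scale_cutoff_cpo <= 0:
        raise ValueError("modulation cutoffs must be positive")
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    rng = np.random.default_rng(seed)
    frame_rate = 200.0  # 5-ms frames
    n_frames = max(8, int(round(duration_s * frame_rate)))
    env = rng.standard_normal((n_frames, N_CHANNELS))

    F = np.fft.fft2(env)
    rates = np.fft.fftfreq(n_frames, 1.0 / frame_rate)
    scales = np.fft.fftfreq(N_CHANNELS, 1.0 / CH_PER_OCTAVE)
    keep = (np.abs(rates)[:, None] <= rate_cutoff_hz) & (np.abs(scales)[None, :] <= scale_cutoff_cpo)
    env = np.real(np.fft.ifft2(F * keep))
    env /= max(env.std(), 1e-12)
    env = np.clip(1.0 + depth * env, 0.0, None)

    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    frame_t = (np.arange(n_frames) + 0.5) / frame_rate
    fc = center_frequencies()
    phases = rng.uniform(0, 2 * np.pi, size=fc.size)
    sig = np.zeros(n)
    for c in range(fc.size):
        a = np.interp(t, frame_t, env[:, c])
        sig += a * np.sin(2 * np.pi * fc[c] * t + phases[c])
    return Waveform(_rms_normalize(sig), fs)


def _raised_cosine_taper(n: int, n_taper: int) -> np.ndarray:
    w = np.ones(n)
    if n_taper > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_taper) / n_taper))
        w[:n_taper] = ramp
        w[-n_taper:] = ramp[::-1]
    return w


def _segment_counts(fractions, n_segments: int) -> np.ndarray:
    """Largest-remainder apportionment of segments to classes."""
    fr = np.asarray(fractions, dtype=float)
    raw = fr * n_segments
    counts = np.floor(raw).astype(int)
    remainder = n_segments - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts


def _gen_class_segment(kind: str, duration_s: float, rng: np.random.Generator) -> np.ndarray:
    """One un-standardized segment from a surrogate class."""
    seed = int(rng.integers(2**31))
    if kind == "speech":
        f0a = rng.uniform(100, 250)
        f0b = f0a * rng.uniform(0.8, 1.25)
        formants = rng.uniform(300, 3000, size=3)
        am = rng.uniform(3, 8)
        wav = gen_harmonic_call([f0a, f0b], formants, am, duration_s, seed=seed)
    elif kind == "vocalization":
        sig = np.zeros(int(round(duration_s * SAMPLE_RATE_HZ)))
        for _ in range(rng.integers(2, 4)):
            rate = float(np.exp(rng.uniform(np.log(2), np.log(32))))
            scale = rng.uniform(0.25, 2.0)
            direction = "down" if rng.random() < 0.5 else "up"
            sig += gen_moving_ripple(
                rate, scale, duration_s, direction, seed=int(rng.integers(2**31))
            ).samples
        return sig
    elif kind == "ambient":
        rate_cut = rng.uniform(4, 16)
        scale_cut = rng.uniform(0.5, 2.0)
        wav = gen_modulated_noise(rate_cut, scale_cut, duration_s, seed=seed)
    else:  # pragma: no cover - internal
        raise ValueError(f"unknown class {kind!r}")
    return wav.samples


CLASS_NAMES = ("speech", "vocalization", "ambient")


def gen_stimulus_ensemble(recipe: StimulusRecipe, return_segments: bool = False):
    """Concatenated ensemble of standardized, tapered 3-s class segments.

    Each segment is standardized to zero mean and unit variance, then
    raised-cosine tapered (``recipe.taper_ms`` per edge) and the segments are
    concatenated in seeded random order.  Class counts honor
    ``recipe.class_fractions`` within one segment (largest remainder).
    """
    n_segments = int(recipe.total_duration_s // recipe.segment_duration_s)
    if n_segments < 1:
        raise ValueError("total duration too short for one segment")
    counts = _segment_counts(recipe.class_fractions, n_segments)

    rng = np.random.default_rng(recipe.seed)
    kinds = [k for k, c in zip(CLASS_NAMES, counts) for _ in range(c)]
    order = rng.permutation(n_segments)

    seg_len = int(round(recipe.segment_duration_s * SAMPLE_RATE_HZ))
    n_taper = int(round(recipe.taper_ms / 1000 * SAMPLE_RATE_HZ))
    taper = _raised_cosine_taper(seg_len, n_taper)

    raw_segments = []
    for kind in kinds:
        seg = _gen_class_segment(kind, recipe.segment_duration_s, rng)[:seg_len]
        seg = seg - seg.mean()
        seg = seg / max(seg.std(), 1e-12)
        raw_segments.append(seg)

    pieces = [raw_segments[i] * taper for i in order]
    wave = Waveform(np.concatenate(pieces), SAMPLE_RATE_HZ)
    if return_segments:
        info = [
            {"kind": kinds[i], "segment": raw_segments[i], "position": int(np.where(order == i)[0][0])}
            for i in range(n_segments)
        ]
        return wave, info
    return wave


def gen_slow_latent_patches(
    D: int,
    T: int,
    n_slow: int,
    n_fast: int,
    mixing_seed: int = 0,
    envelope_sigma: float = 10.0,
):
    """Latent-factor patch data with a planted slow subspace.

    Columns are x_t = A s_t with orthonormal mixing A.  Slow sources are
    Rademacher carriers modulated by a smooth positive envelope (lag-1 energy
    autocorrelation > 0.9); fast sources are white Gaussian.  All sources have
    unit variance.  Returns ``(PatchMatrix, A_slow, sources)`` where
    ``A_slow`` spans the true slow subspace.
    """
    from .patches import PatchMatrix

    if D < 1:
        raise ValueError("D must be >= 1")
    if n_slow + n_fast > D:
        raise ValueError("n_slow + n_fast must not exceed D")
    rng = np.random.default_rng(mixing_seed)

    sources = np.zeros((n_slow + n_fast, T))
    for i in range(n_slow):
        env = gaussian_filter1d(rng.standard_normal(T), envelope_sigma, mode="wrap")
        env = np.abs(env) + 0.05
        s = env * rng.choice([-1.0, 1.0], size=T)
        sources[i] = s / s.std()
    for i in range(n_slow, n_slow + n_fast):
        s = rng.standard_normal(T)
        sources[i] = s / s.std()

    A = np.linalg.qr(rng.standard_normal((D, n_slow + n_fast)))[0]
    X = A @ sources
    pm = PatchMatrix(X=X, patch_shape=None, preprocessed=False)
    return pm, A[:, :n_slow], sources


def gen_sparse_latent_patches(D: int, T: int, seed: int = 0):
    """Orthonormally mixed unit-variance Laplacian sources (sparse-recovery fixture).

    Returns ``(PatchMatrix, A, sources)`` with ``X = A @ sources`` and A an
    orthonormal D x D mixing matrix.
    """
    from .patches import PatchMatrix

    if D < 1:
        raise ValueError("D must be >= 1")
    rng = np.random.default_rng(seed)
    sources = rng.laplace(scale=1.0 / np.sqrt(2.0), size=(D, T))
    sources /= sources.std(axis=1, keepdims=True)
    A = np.linalg.qr(rng.standard_normal((D, D)))[0]
    return PatchMatrix(X=A @ sources, patch_shape=None, preprocessed=False), A, sources
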