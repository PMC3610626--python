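"""Characterization of individual STRFs.

An STRF patch is a (frames x channels) = (time x log-frequency) matrix.
Metrics:

* separability index SPI = 1 - sigma_1^2 / sum_k sigma_k^2 from the patch
  SVD: 0 for a rank-1 (time (x) frequency separable) STRF, approaching 1 for
  noisy, high-rank patterns.
* modulation transfer function (MTF): magnitude of the 2D Fourier transform
  of the patch after zeroing entries within +-1 SD of zero, collapsed to the
  scale >= 0 half-plane with signed rate.  With 50 x 60 patches the rate
  step is 4 Hz and the scale step 1/6 cyc/oct.  (Nyquist bins, which have no
  symmetric partner in the half-plane, are discarded.)
* best rate / best scale: location of the MTF peak (DC bin excluded).
* rate and scale modulation profiles with upper 6-dB amplitude cutoffs.
* directionality index DSI = (R1 - R2) / (R1 + R2) over quadrant energies;
  with the patch oriented time-rightward / frequency-upward, positive DSI
  marks a preference for downward-moving spectro-temporal sweeps.
* compactness: isoperimetric quotient 4 pi A / P^2 of the 10-dB ellipse of a
  least-squares 2D Gaussian envelope fit (1 for a circular, localized STRF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .grids import CH_PER_OCTAVE, FRAME_MS

__all__ = [
    "ModulationTransferFunction",
    "ModulationProfiles",
    "STRFMetrics",
    "separability_index",
    "compute_mtf",
    "best_rate_scale",
    "modulation_profiles",
    "directionality_index",
    "compactness",
    "compute_metrics",
]


@dataclass
class ModulationTransferFunction:
    """|2D Fourier| magnitude over (signed rate in Hz, scale >= 0 in cyc/oct)."""

    magnitude: np.ndarray  # (n_rates, n_scales)
    rates_hz: np.ndarray  # ascending, signed
    scales_cpo: np.ndarray  # ascending, >= 0

    def __post_init__(self):
        if np.any(self.magnitude < 0):
            raise ValueError("MTF magnitudes must be non-negative")


@dataclass
class ModulationProfiles:
    rate_axis_hz: np.ndarray
    rate_profile: np.ndarray
    scale_axis_cpo: np.ndarray
    scale_profile: np.ndarray
    rate_cutoff6db_hz: float
    scale_cutoff6db_cpo: float


@dataclass
class STRFMetrics:
    spi: float
    br_hz: float
    bs_cpo: float
    dsi: float
    compactness: float
    rate_cutoff6db_hz: float
    scale_cutoff6db_cpo: float


def separability_index(patch: np.ndarray) -> float:
    """SPI = 1 - sigma_1^2 / sum sigma_k^2; invariant to transposition and scaling."""
    patch = np.asarray(patch, dtype=np.float64)
    s = np.linalg.svd(patch, compute_uv=False)
    total = float((s**2).sum())
    if total == 0:
        raise ValueError("all-zero patch has undefined separability")
    return float(1.0 - s[0] ** 2 / total)


def _fourier_halfplane(patch: np.ndarray, frame_ms: float, ch_per_octave: int):
    """|FFT2| of a (time x frequency) patch on (signed rate, scale>=0) axes.

    Nyquist rows/columns are dropped so every retained (r, s>0) bin has its
    conjugate-symmetric partner at (-r, -s) in the discarded half-plane.
    """
    n_t, n_f = patch.shape
    mag = np.abs(np.fft.fft2(patch))
    rates = np.fft.fftfreq(n_t, frame_ms / 1000.0)
    scales = np.fft.fftfreq(n_f, 1.0 / ch_per_octave)
    mag = np.fft.fftshift(mag)
    rates = np.fft.fftshift(rates)
    scales = np.fft.fftshift(scales)
    keep_r = ~((n_t % 2 == 0) & (rates == rates.min()))
    keep_s = scales >= 0
    return mag[np.ix_(keep_r, keep_s)], rates[keep_r], scales[keep_s]


def compute_mtf(
    patch: np.ndarray,
    threshold_sd: float = 1.0,
    frame_ms: float = FRAME_MS,
    ch_per_octave: int = CH_PER_OCTAVE,
) -> ModulationTransferFunction:
    """MTF of a thresholded STRF patch.

    Entries with |value| <= threshold_sd * SD(patch) are zeroed before the
    2D Fourier transform (SD over the full patch, zeros included).  A patch
    that thresholds away entirely yields an all-zero MTF with a warning.
    """
    patch = np.asarray(patch, dtype=np.float64)
    sd = patch.std()
    if sd == 0:
        # a constant patch carries no spectro-temporal structure at all
        thr = np.zeros_like(patch)
    else:
        thr = np.where(np.abs(patch) > threshold_sd * sd, patch, 0.0)
    if not np.any(thr):
        warnings.warn("patch fully thresholded away; MTF is all-zero")
    mag, rates, scales = _fourier_halfplane(thr, frame_ms, ch_per_octave)
    return ModulationTransferFunction(magnitude=mag, rates_hz=rates, scales_cpo=scales)


def best_rate_scale(mtf: ModulationTransferFunction):
    """(|rate|, scale) of the global MTF magnitude peak.

    The DC bin (rate 0, scale 0) is excluded; ties break toward smaller
    |rate| then smaller scale.  An all-zero MTF yields (nan, nan).
    """
    mag = mtf.magnitude.copy()
    dc_r = np.where(mtf.rates_hz == 0)[0]
    dc_s = np.where(mtf.scales_cpo == 0)[0]
    if dc_r.size and dc_s.size:
        mag[dc_r[0], dc_s[0]] = -np.inf
    peak = mag.max()
    if not np.isfinite(peak) or peak <= 0:
        warnings.warn("MTF has no non-zero peak; best rate/scale undefined")
        return float("nan"), float("nan")
    ri, si = np.where(mag == peak)
    cand = sorted(zip(ri, si), key=lambda ij: (abs(mtf.rates_hz[ij[0]]), mtf.scales_cpo[ij[1]]))
    i, j = cand[0]
    return float(abs(mtf.rates_hz[i])), float(mtf.scales_cpo[j])


def _upper_cutoff(axis: np.ndarray, profile: np.ndarray, level: float):
    """Highest axis value where the profile crosses ``level`` above its peak,
    linearly interpolated between bins."""
    peak = int(np.argmax(profile))
    above = profile >= level
    j = len(profile) - 1
    while j > peak and not above[j]:
        j -= 1
    # j is now the last index >= level at/after the peak
    if j == len(profile) - 1:
        warnings.warn("profile never falls 6 dB below its peak; cutoff set to axis maximum")
        return float(axis[-1])
    p0, p1 = profile[j], profile[j + 1]
    frac = (p0 - level) / (p0 - p1) if p0 != p1 else 0.0
    return float(axis[j] + frac * (axis[j + 1] - axis[j]))


def modulation_profiles(
    mtf: ModulationTransferFunction, cutoff_db: float = 6.0, scale_kind: str = "amplitude"
) -> ModulationProfiles:
    """Folded rate profile, scale profile, and upper 6-dB cutoffs.

    The rate profile merges +-rate bins and sums over scale; the scale
    profile sums over signed rate.  Both are normalized to peak 1.  The
    cutoff is the highest frequency above the peak where the profile crosses
    the -6 dB level (amplitude convention by default: 10^(-6/20) ~ 0.501).
    """
    if not np.any(mtf.magnitude):
        raise ValueError("all-zero MTF has no modulation profiles")
    abs_rates = np.abs(mtf.rates_hz)
    rate_axis = np.unique(abs_rates)
    rate_profile = np.array(
        [mtf.magnitude[abs_rates == r, :].sum() for r in rate_axis]
    )
    scale_profile = mtf.magnitude.sum(axis=0)

    rate_profile = rate_profile / rate_profile.max()
    scale_profile = scale_profile / scale_profile.max()
    if scale_kind == "amplitude":
        level = 10.0 ** (-cutoff_db / 20.0)
    elif scale_kind == "power":
        level = 10.0 ** (-cutoff_db / 10.0)
    else:
        raise ValueError("scale_kind must be 'amplitude' or 'power'")
    return ModulationProfiles(
        rate_axis_hz=rate_axis,
        rate_profile=rate_profile,
        scale_axis_cpo=mtf.scales_cpo,
        scale_profile=scale_profile,
        rate_cutoff6db_hz=_upper_cutoff(rate_axis, rate_profile, level),
        scale_cutoff6db_cpo=_upper_cutoff(mtf.scales_cpo, scale_profile, level),
    )


def directionality_index(mtf: ModulationTransferFunction) -> float:
    """DSI = (R1 - R2)/(R1 + R2) with quadrant energies R1 (rate>0, scale>0)
    and R2 (rate<0, scale>0); positive values mark downward-preferring STRFs."""
    E = mtf.magnitude**2
    pos_s = mtf.scales_cpo > 0
    r1 = float(E[np.ix_(mtf.rates_hz > 0, pos_s)].sum())
    r2 = float(E[np.ix_(mtf.rates_hz < 0, pos_s)].sum())
    if r1 + r2 == 0:
        warnings.warn("no off-axis modulation energy; DSI undefined")
        return float("nan")
    return (r1 - r2) / (r1 + r2)


def _gaussian_moments(w: np.ndarray):
    """Centroid and second-moment covariance of a non-negative image."""
    ti, fi = np.indices(w.shape)
    tot = w.sum()
    t0, f0 = (w * ti).sum() / tot, (w * fi).sum() / tot
    ctt = (w * (ti - t0) ** 2).sum() / tot
    cff = (w * (fi - f0) ** 2).sum() / tot
    ctf = (w * (ti - t0) * (fi - f0)).sum() / tot
    return t0, f0, np.array([[ctt, ctf], [ctf, cff]])


def compactness(patch: np.ndarray, threshold_sd: float = 1.0) -> float:
    """Isoperimetric quotient q = 4 pi A / P^2 of the fitted 10-dB ellipse.

    A single 2D Gaussian envelope is least-squares fit to the magnitude of
    the thresholded patch (initialized from image moments); the isoline 10 dB
    below the envelope maximum is an ellipse whose area A and perimeter P
    (Ramanujan approximation) give q, with q = 1 for a circular region and
    q -> 0 for elongated ones.  Returns nan when no fit is possible.
    """
    patch = np.asarray(patch, dtype=np.float64)
    sd = patch.std()
    w = np.abs(np.where(np.abs(patch) > threshold_sd * sd, patch, 0.0))
    if not np.any(w):
        warnings.warn("patch fully thresholded away; compactness undefined")
        return float("nan")
    t0, f0, cov = _gaussian_moments(w)
    # Parameterize the inverse covariance through its Cholesky factor so the
    # fitted quadratic form stays positive definite.
    cov = cov + 1e-6 * np.eye(2)
    try:
        L0 = np.linalg.cholesky(np.linalg.inv(cov))
    except np.linalg.LinAlgError:
        warnings.warn("degenerate moment covariance; compactness undefined")
        return float("nan")
    ti, fi = np.indices(patch.shape)

    def model(p):
        amp, tc, fc, l11, l21, l22 = p
        u, v = ti - tc, fi - fc
        q1 = l11 * u + l21 * v
        q2 = l22 * v
        return amp * np.exp(-0.5 * (q1**2 + q2**2))

    p0 = np.array([w.max(), t0, f0, L0[0, 0], L0[1, 0], L0[1, 1]])
    try:
        res = optimize.least_squares(
            lambda p: (model(p) - w).ravel(), p0, max_nfev=200, method="lm"
        )
    except Exception:
        warnings.warn("Gaussian envelope fit failed; compactness undefined")
        return float("nan")
    amp, _, _, l11, l21, l22 = res.x
    if not np.all(np.isfinite(res.x)) or amp <= 0 or abs(l11) < 1e-12 or abs(l22) < 1e-12:
        warnings.warn("Gaussian envelope fit degenerate; compactness undefined")
        return float("nan")
    Lf = np.array([[l11, 0.0], [l21, l22]])
    cov_fit = np.linalg.inv(Lf @ Lf.T)
    lam = np.linalg.eigvalsh(cov_fit)
    if np.any(lam <= 0):
        warnings.warn("non-positive fitted covariance; compactness undefined")
        return float("nan")
    rho = np.sqrt(2.0 * np.log(10.0 ** (10.0 / 20.0)))  # 10-dB amplitude drop
    a, b = rho * np.sqrt(lam[1]), rho * np.sqrt(lam[0])
    area = np.pi * a * b
    perim = np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b)))
    return float(4 * np.pi * area / perim**2)


def compute_metrics(patch: np.ndarray, threshold_sd: float = 1.0) -> STRFMetrics:
    """All per-STRF metrics for one (time x frequency) patch."""
    spi = separability_index(patch)
    mtf = compute_mtf(patch, threshold_sd=threshold_sd)
    if np.any(mtf.magnitude):
        br, bs = best_rate_scale(mtf)
        prof = modulation_profiles(mtf)
        rc, sc = prof.rate_cutoff6db_hz, prof.scale_cutoff6db_cpo
        dsi = directionality_index(mtf)
    else:
        br = bs = rc = sc = dsi = float("nan")
    q = compactness(patch, threshold_sd=threshold_sd)
    return STRFMetrics(
        spi=spi, br_hz=br, bs_cpo=bs, dsi=dsi, compactness=q,
        rate_cutoff6db_hz=rc, scale_cutoff6db_cpo=sc,
    )
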