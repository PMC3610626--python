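"""Population-level analyses of STRF ensembles.

* ensemble MTF (eMTF): the mean of per-STRF modulation transfer functions,
  with isoline contours at a stated fraction of its maximum.
* activation persistence: per neuron, the durations of maximal runs where
  |y_i(t)| exceeds one temporal standard deviation; the top 10% of neurons
  by median activation form the "most persistent" subset.
* average population response histogram: the per-time histogram of the
  instantaneous population response, averaged over the stimulus duration.
* average stimulus 2D modulation profile: mean |FFT2| over non-overlapping
  250-ms spectrogram patches, on the same (rate, scale) axes as the MTFs.
* nearest-neighbor similarity KL: symmetric Kullback-Leibler divergence
  between the NN-similarity distributions of two ensembles against a common
  reference set.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .audspec import AuditorySpectrogram
from .grids import CH_PER_OCTAVE, FRAME_MS
from .strfmetrics import ModulationTransferFunction, _fourier_halfplane, compute_mtf

__all__ = [
    "ActivationSummary",
    "ensemble_mtf",
    "activation_times",
    "population_response_histogram",
    "histogram_moments",
    "stimulus_modulation_profile",
    "nn_similarities",
    "symmetric_kl",
    "nn_similarity_kl",
]


@dataclass
class ActivationSummary:
    """Per-neuron activation-event statistics (times in ms, multiples of the frame)."""

    median_ms: np.ndarray
    iqr_ms: np.ndarray
    order: np.ndarray  # neuron indices by descending median
    persistent: np.ndarray  # top 10% most persistent neuron indices


def ensemble_mtf(patches, threshold_sd: float = 1.0, contour_level: float = 0.65):
    """Mean MTF across STRFs plus isoline contours at ``contour_level * max``.

    ``patches`` is an iterable of (time x frequency) STRF patches or a
    (K, frames, channels) array.  Returns ``(ModulationTransferFunction,
    contours)`` where contours are polylines in (rate Hz, scale cyc/oct)
    coordinates.
    """
    patches = list(np.asarray(p) for p in patches)
    if len(patches) == 0:
        raise ValueError("empty ensemble")
    mtfs = [compute_mtf(p, threshold_sd=threshold_sd) for p in patches]
    mag = np.mean([m.magnitude for m in mtfs], axis=0)
    emtf = ModulationTransferFunction(
        magnitude=mag, rates_hz=mtfs[0].rates_hz, scales_cpo=mtfs[0].scales_cpo
    )
    contours = mtf_contours(emtf, contour_level)
    return emtf, contours


def mtf_contours(mtf: ModulationTransferFunction, level: float = 0.65):
    """Isoline polylines of an MTF at ``level * max`` in axis coordinates."""
    if mtf.magnitude.max() <= 0:
        return []
    raw = measure.find_contours(mtf.magnitude, level * mtf.magnitude.max())
    out = []
    for poly in raw:
        r = np.interp(poly[:, 0], np.arange(mtf.rates_hz.size), mtf.rates_hz)
        s = np.interp(poly[:, 1], np.arange(mtf.scales_cpo.size), mtf.scales_cpo)
        out.append(np.column_stack([r, s]))
    return out


def _run_lengths(active: np.ndarray) -> np.ndarray:
    """Lengths of maximal True runs in a boolean sequence."""
    if not active.any():
        return np.array([], dtype=int)
    padded = np.concatenate([[0], active.view(np.int8), [0]])
    d = np.diff(padded)
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0]
    return ends - starts


def activation_times(
    Y: np.ndarray,
    threshold_sd: float = 1.0,
    frame_ms: float = FRAME_MS,
    two_sided: bool = True,
) -> ActivationSummary:
    """Durations of supra-threshold response runs, per neuron.

    A neuron is "active" while its response magnitude (or signed response,
    ``two_sided=False``) exceeds ``threshold_sd`` times its own temporal
    standard deviation.  Event durations are run length x frame_ms; the
    summary reports the median and interquartile range over events, neurons
    ordered by descending median, and the top-10% persistent subset
    (ceil(0.1 K) neurons).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    K, T = Y.shape
    if T < 2:
        raise ValueError("need at least two time points")
    med = np.zeros(K)
    iqr = np.zeros(K)
    for i in range(K):
        thr = threshold_sd * Y[i].std()
        sig = np.abs(Y[i]) if two_sided else Y[i]
        durations = _run_lengths(sig > thr) * frame_ms
        if durations.size:
            med[i] = float(np.median(durations))
            q75, q25 = np.percentile(durations, [75, 25])
            iqr[i] = float(q75 - q25)
    order = np.argsort(-med, kind="stable")
    n_top = math.ceil(0.1 * K)
    return ActivationSummary(median_ms=med, iqr_ms=iqr, order=order, persistent=order[:n_top])


def population_response_histogram(
    Y: np.ndarray,
    bins: np.ndarray | None = None,
    include_mask=None,
    normalize_unit_variance: bool = False,
):
    """Average over time of the per-time population response histogram.

    With fixed bin edges the average of per-time histograms equals the pooled
    histogram of all included responses.  Values are clipped into the bin
    range so the masses sum to 1.  ``include_mask`` restricts to a neuron
    subset; ``normalize_unit_variance`` rescales each neuron's response to
    unit temporal variance first (for comparison ensembles such as principal
    components or random filters).

    Returns ``(bin_edges, masses)``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    if Y.shape[0] < 2:
        raise ValueError("population histogram needs K >= 2 neurons")
    if include_mask is not None:
        Y = Y[np.asarray(include_mask)]
        if Y.size == 0 or Y.shape[0] == 0:
            raise ValueError("include_mask selects no neurons")
    if normalize_unit_variance:
        sd = Y.std(axis=1, keepdims=True)
        Y = Y / np.where(sd > 0, sd, 1.0)
    if bins is None:
        bins = np.linspace(-6.0, 6.0, 102)  # 101 uniform bins
    vals = np.clip(Y.ravel(), bins[0], bins[-1])
    counts, edges = np.histogram(vals, bins=bins)
    return edges, counts / counts.sum()


def histogram_moments(edges: np.ndarray, masses: np.ndarray):
    """Mean, variance, and kurtosis implied by a (normalized) histogram."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = float((masses * centers).sum())
    v = float((masses * (centers - m) ** 2).sum())
    mu4 = float((masses * (centers - m) ** 4).sum())
    kurt = mu4 / v**2 if v > 0 else float("nan")
    return m, v, kurt


def stimulus_modulation_profile(
    spec: AuditorySpectrogram, win_ms: float = 250.0
) -> ModulationTransferFunction:
    """Average |FFT2| magnitude over non-overlapping 250-ms spectrogram patches."""
    frames_per_patch = int(round(win_ms / spec.frame_ms))
    n_patches = spec.n_frames // frames_per_patch
    if n_patches < 1:
        raise ValueError("spectrogram shorter than one patch window")
    acc = None
    for p in range(n_patches):
        patch = spec.values[p * frames_per_patch : (p + 1) * frames_per_patch]
        mag, rates, scales = _fourier_halfplane(patch, spec.frame_ms, CH_PER_OCTAVE)
        acc = mag if acc is None else acc + mag
    return ModulationTransferFunction(magnitude=acc / n_patches, rates_hz=rates, scales_cpo=scales)


def nn_similarities(patches, reference, exclude_self: bool = False) -> np.ndarray:
    """Each STRF's maximum cross-correlation similarity to a reference set."""
    from .clustering import strf_similarity

    patches = list(patches)
    reference = list(reference)
    same = exclude_self or (len(patches) == len(reference) and all(a is b for a, b in zip(patches, reference)))
    out = np.empty(len(patches))
    for i, p in enumerate(patches):
        sims = [strf_similarity(p, q) for j, q in enumerate(reference) if not (same and i == j)]
        if not sims:
            raise ValueError("reference set empty after self-exclusion")
        out[i] = max(sims)
    return out


def symmetric_kl(p: np.ndarray, q: np.ndarray, smoothing: float = 1e-6) -> float:
    """KL(p||q) + KL(q||p) in nats, with additive smoothing before normalization."""
    p = np.asarray(p, dtype=np.float64) + smoothing
    q = np.asarray(q, dtype=np.float64) + smoothing
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)) + np.sum(q * np.log(q / p)))


def nn_similarity_kl(
    ensemble_a,
    ensemble_b,
    reference=None,
    bins: np.ndarray | None = None,
    smoothing: float = 1e-6,
) -> float:
    """Symmetric KL divergence between two ensembles' NN-similarity distributions.

    For each STRF in each ensemble, its nearest-neighbor similarity is the
    maximum cross-correlation similarity to the reference set, with self
    exclusion whenever an ensemble is compared against itself.  When no
    reference is given, each ensemble is compared against the other
    (cross-NN), which is symmetric and yields divergence 0 for identical
    ensembles.  Both NN similarity samples are histogrammed on shared bins
    and compared with the smoothed symmetric KL divergence (nats).
    """
    a = list(ensemble_a)
    b = list(ensemble_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each ensemble needs at least 2 STRFs")
    if reference is None:
        sa = nn_similarities(a, b)
        sb = nn_similarities(b, a)
    else:
        ref = list(reference)
        sa = nn_similarities(a, ref)
        sb = nn_similarities(b, ref)
    if bins is None:
        bins = np.linspace(0.0, 1.0, 21)
    ha, _ = np.histogram(np.clip(sa, 0, 1), bins=bins)
    hb, _ = np.histogram(np.clip(sb, 0, 1), bins=bins)
    if (ha > 0).sum() <= 1 and (hb > 0).sum() <= 1 and np.array_equal(ha > 0, hb > 0):
        warnings.warn("degenerate single-bin NN-similarity distributions")
        return 0.0
    return symmetric_kl(ha, hb, smoothing=smoothing)
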