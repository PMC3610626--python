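"""Spectro-temporal patch extraction, normalization, and PCA whitening.

250-ms patches (50 frames x 60 channels, D = 3000) are slid over the
auditory spectrogram every 5 ms and stacked temporal-major into columns of a
D x T matrix: element (frame i, channel j) of a patch sits at stacked index
i * n_channels + j.  Each column then has its scalar mean removed and is
scaled to unit norm.  Enforcing unit-variance, mutually uncorrelated filter
responses is equivalent to learning orthonormal filters on a whitened version
of the patch matrix: with sample covariance C = (1/T) X X^T = E L E^T, the
whitened data Z = L^{-1/2} E^T X has identity covariance, and any orthonormal
B in whitened coordinates maps back to raw-coordinate filters
H = E L^{-1/2} B whose responses H^T X = B^T Z also have identity covariance.
Dimensionality is reduced to the leading M principal components capturing a
target fraction (default 95%) of the variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .audspec import AuditorySpectrogram
from .grids import FRAME_MS, PATCH_FRAMES

__all__ = [
    "PatchMatrix",
    "WhiteningModel",
    "extract_patches",
    "preprocess_patches",
    "fit_whitening",
    "apply_whitening",
    "unwhiten_filters",
    "unstack_patch",
]


@dataclass
class PatchMatrix:
    """Column-stacked patch vectors.

    ``X`` is D x T (one column per patch / hop).  ``patch_shape`` is
    (frames_per_patch, n_channels) for spectro-temporal data, or None for
    abstract latent data.  ``preprocessed`` marks mean-removed, unit-norm
    columns.
    """

    X: np.ndarray
    patch_shape: tuple | None = (PATCH_FRAMES, 60)
    hop_ms: float = FRAME_MS
    preprocessed: bool = False

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (D x T)")
        if self.patch_shape is not None and int(np.prod(self.patch_shape)) != self.X.shape[0]:
            raise ValueError("patch_shape inconsistent with stacked dimension D")

    @property
    def D(self) -> int:
        return self.X.shape[0]

    @property
    def T(self) -> int:
        return self.X.shape[1]


@dataclass
class WhiteningModel:
    """Retained principal subspace of the patch covariance.

    ``eigvecs`` (D x M) and ``eigvals`` (M, descending, positive) come from
    the eigendecomposition of the 1/T-normalized sample covariance; M is the
    smallest count whose cumulative variance reaches ``var_fraction_target``.
    """

    eigvecs: np.ndarray
    eigvals: np.ndarray
    var_fraction_target: float
    var_captured: float

    def __post_init__(self):
        if np.any(self.eigvals <= 0) or np.any(np.diff(self.eigvals) > 0):
            raise ValueError("eigenvalues must be positive and non-increasing")

    @property
    def M(self) -> int:
        return self.eigvals.size

    @property
    def D(self) -> int:
        return self.eigvecs.shape[0]


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, PatchMatrix):
        return data.X
    return np.asarray(data, dtype=np.float64)


def extract_patches(spec: AuditorySpectrogram, win_ms: float = 250.0, hop_ms: float = FRAME_MS) -> PatchMatrix:
    """Sliding spectro-temporal patches, one column per hop.

    A spectrogram with F frames yields T = F - frames_per_patch + 1 columns
    (hop of one frame); each column stacks the patch's spectral vectors in
    temporal order.
    """
    frames_per_patch = int(round(win_ms / spec.frame_ms))
    hop_frames = max(1, int(round(hop_ms / spec.frame_ms)))
    if spec.n_frames < frames_per_patch:
        raise ValueError(
            f"spectrogram has {spec.n_frames} frames; need at least {frames_per_patch}"
        )
    windows = sliding_window_view(spec.values, frames_per_patch, axis=0)[::hop_frames]
    # windows: (T, n_channels, frames_per_patch) -> temporal-major stacking
    T = windows.shape[0]
    X = windows.transpose(0, 2, 1).reshape(T, -1).T.copy()
    return PatchMatrix(X=X, patch_shape=(frames_per_patch, spec.n_channels), hop_ms=hop_frames * spec.frame_ms)


def unstack_patch(column: np.ndarray, patch_shape: tuple) -> np.ndarray:
    """Inverse of the temporal-major stacking: column -> (frames, channels)."""
    return np.asarray(column).reshape(patch_shape)


def preprocess_patches(pm: PatchMatrix) -> PatchMatrix:
    """Remove each column's scalar mean and scale it to unit Euclidean norm.

    Columns that are (numerically) zero after mean removal are dropped with a
    warning; an all-zero input is an error.
    """
    X = pm.X - pm.X.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(X, axis=0)
    tol = 1e-10 * max(norms.max(), 1e-300)
    keep = norms > tol
    if not keep.any():
        raise ValueError("all patch columns are zero after mean removal")
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero patch column(s)")
        X = X[:, keep]
        norms = norms[keep]
    X = X / norms
    return PatchMatrix(X=X, patch_shape=pm.patch_shape, hop_ms=pm.hop_ms, preprocessed=True)


def fit_whitening(pm, var_fraction: float = 0.95) -> WhiteningModel:
    """Eigendecompose the sample covariance and retain the leading components.

    M is the smallest count of principal components whose cumulative variance
    fraction reaches ``var_fraction``; eigenvalues below 1e-12 of the largest
    are discarded as numerical rank deficiency.
    """
    X = _as_matrix(pm)
    if not (0 < var_fraction <= 1.0):
        raise ValueError("var_fraction must lie in (0, 1]")
    T = X.shape[1]
    C = (X @ X.T) / T
    evals, evecs = np.linalg.eigh(C)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    valid = evals > 1e-12 * max(evals[0], 0.0)
    evals, evecs = evals[valid], evecs[:, valid]
    if evals.size == 0:
        raise ValueError("covariance is numerically zero")
    frac = np.cumsum(evals) / evals.sum()
    M = int(np.searchsorted(frac, var_fraction - 1e-12) + 1)
    M = min(M, evals.size)
    return WhiteningModel(
        eigvecs=evecs[:, :M],
        eigvals=evals[:M],
        var_fraction_target=var_fraction,
        var_captured=float(frac[M - 1]),
    )


def apply_whitening(pm, model: WhiteningModel) -> np.ndarray:
    """Z = L^{-1/2} E^T X (M x T); on the fitting data cov(Z) = I."""
    X = _as_matrix(pm)
    if X.shape[0] != model.D:
        raise ValueError(
            f"dimension mismatch: data has D={X.shape[0]}, model expects D={model.D} "
            "(applying whitening twice is a pipeline error)"
        )
    return (model.eigvecs.T @ X) / np.sqrt(model.eigvals)[:, None]


def unwhiten_filters(B: np.ndarray, model: WhiteningModel) -> np.ndarray:
    """Map orthonormal whitened-space filters B (M x K) to raw STRFs H = E L^{-1/2} B.

    The responses satisfy H^T X = B^T Z, so the raw filters inherit the
    unit-variance / decorrelation response constraints.
    """
    B = np.asarray(B, dtype=np.float64)
    if B.shape[0] != model.M:
        raise ValueError(f"B has {B.shape[0]} rows, model retains M={model.M} components")
    res = np.linalg.norm(B.T @ B - np.eye(B.shape[1]))
    if res > 1e-8:
        raise ValueError(f"B does not have orthonormal columns (residual {res:.2e})")
    return model.eigvecs @ (B / np.sqrt(model.eigvals)[:, None])
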