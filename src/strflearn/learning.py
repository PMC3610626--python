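"""Objectives, analytic gradients, and projected-gradient learning of STRF ensembles.

Two population coding objectives are maximized over an ensemble of K linear
filters with orthonormal columns:

* sustained firing: Psi_s = sum_i sum_{n=1..N} w_n <y_i^2(t) y_i^2(t-n)>_t,
  the weighted sum of lagged correlations between response energies, with
  linearly decaying lag weights w_n.  Large Psi_s means response energy
  varies smoothly (is sustained) over the correlation interval N.
* population sparsity: Psi_k = <mu4(t) / sigma^4(t)>_t, the time-averaged raw
  kurtosis of the instantaneous population response distribution; large
  values indicate a peaked, heavy-tailed (sparse) code.

The constraint set is the Stiefel manifold B^T B = I.  Under *response*
constraints the data are whitened first, so orthonormality of B in whitened
coordinates enforces unit-variance, mutually uncorrelated responses; under
*shape* constraints B lives in raw patch coordinates and the filters
themselves form an orthonormal basis.  Optimization is Rosen's gradient
projection: take a gradient ascent step, project back onto the constraint
set with the orthogonal Procrustes projection A (A^T A)^{-1/2} = U V^T, and
halve the step while the objective would decrease.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import FRAME_MS
from .patches import PatchMatrix, WhiteningModel, _as_matrix, unwhiten_filters

__all__ = [
    "ObjectiveConfig",
    "STRFEnsemble",
    "TraceRecord",
    "compute_responses",
    "sustained_objective",
    "sustained_gradient",
    "kurtosis_objective",
    "kurtosis_gradient",
    "procrustes_project",
    "fit_ensemble",
    "per_filter_contribution",
]

#: correlation intervals (ms) studied by default
DEFAULT_N_MS_GRID = (10, 25, 50, 125, 250, 500, 1000, 2000)


@dataclass
class ObjectiveConfig:
    """Which objective to maximize, and the lag structure of the sustained one.

    ``N_ms`` is the correlation interval; with 5-ms frames it translates to
    N_lags = N_ms / frame_ms lags, weighted by linearly decaying
    w_n = (N_lags - n + 1) / N_lags for n = 1..N_lags.  ``kind='sparse'``
    ignores the lag settings.
    """

    kind: str = "sustained"
    N_ms: float = 125.0
    frame_ms: float = FRAME_MS
    weights: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("sustained", "sparse"):
            raise ValueError("kind must be 'sustained' or 'sparse'")
        if self.kind == "sustained":
            n_lags = self.N_ms / self.frame_ms
            if n_lags < 1 or abs(n_lags - round(n_lags)) > 1e-9:
                raise ValueError("N_ms must be a positive multiple of frame_ms")
            if self.weights is None:
                n = round(n_lags)
                self.weights = (n - np.arange(1, n + 1) + 1) / n
            else:
                self.weights = np.asarray(self.weights, dtype=np.float64)
                if np.any(self.weights <= 0) or np.any(np.diff(self.weights) > 0):
                    raise ValueError("weights must be positive and non-increasing")

    @property
    def N_lags(self) -> int:
        return len(self.weights) if self.kind == "sustained" else 0


@dataclass
class STRFEnsemble:
    """K learned filters with orthonormal columns in their coordinate space.

    ``coordinate_space`` is 'whitened' (response mode) or 'raw' (shape mode);
    for response mode the raw-coordinate STRFs recovered through the
    whitening model are stored in ``strfs`` (D x K) when available.
    """

    filters: np.ndarray
    coordinate_space: str
    constraint_mode: str
    objective: ObjectiveConfig
    seed: int
    patch_shape: tuple | None = None
    strfs: np.ndarray | None = None

    def __post_init__(self):
        res = np.linalg.norm(self.filters.T @ self.filters - np.eye(self.K))
        if res > 1e-6:
            raise ValueError(f"filters are not orthonormal (residual {res:.2e})")

    @property
    def K(self) -> int:
        return self.filters.shape[1]

    def strf_patches(self) -> np.ndarray:
        """Raw-coordinate STRFs reshaped to (K, frames, channels)."""
        H = self.strfs if self.strfs is not None else self.filters
        if self.patch_shape is None:
            raise ValueError("ensemble has no spectro-temporal patch shape")
        return H.T.reshape(self.K, *self.patch_shape)


@dataclass
class TraceRecord:
    """Per-iteration optimization diagnostics (accepted iterations only)."""

    objectives: list = field(default_factory=list)
    residuals: list = field(default_factory=list)
    halvings: list = field(default_factory=list)
    stop_reason: str = ""


def compute_responses(ensemble, data) -> np.ndarray:
    """Instantaneous firing-rate proxies Y = filters^T data (K x T)."""
    W = ensemble.filters if isinstance(ensemble, STRFEnsemble) else np.asarray(ensemble)
    X = _as_matrix(data)
    if W.shape[0] != X.shape[0]:
        raise ValueError(
            f"coordinate mismatch: filters have dim {W.shape[0]}, data has dim {X.shape[0]}"
        )
    return W.T @ X


def sustained_objective(Y: np.ndarray, config: ObjectiveConfig) -> float:
    """Weighted sum over lags of time-averaged products of lagged response energies."""
    return float(_sustained_per_filter(Y, config).sum())


def _sustained_per_filter(Y: np.ndarray, config: ObjectiveConfig) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=np.float64))
    T = Y.shape[1]
    if config.kind != "sustained":
        raise ValueError("config.kind must be 'sustained'")
    if T <= config.N_lags:
        raise ValueError(f"need T > N_lags ({config.N_lags}); got T={T}")
    E = Y**2
    scores = np.zeros(Y.shape[0])
    for n, w in enumerate(config.weights, start=1):
        scores += w * (E[:, n:] * E[:, :-n]).mean(axis=1)
    return scores


def sustained_gradient(B: np.ndarray, Z, config: ObjectiveConfig) -> np.ndarray:
    """Analytic gradient of the sustained objective w.r.t. B, through Y = B^T Z."""
    Z = _as_matrix(Z)
    Y = B.T @ Z
    T = Y.shape[1]
    if T <= config.N_lags:
        raise ValueError(f"need T > N_lags ({config.N_lags}); got T={T}")
    E = Y**2
    G = np.zeros_like(Y)
    for n, w in enumerate(config.weights, start=1):
        c = 2.0 * w / (T - n)
        G[:, n:] += c * Y[:, n:] * E[:, :-n]
        G[:, :-n] += c * Y[:, :-n] * E[:, n:]
    return Z @ G.T


def kurtosis_objective(Y: np.ndarray) -> float:
    """Time-averaged raw kurtosis of the instantaneous population distribution.

    Time points where the population variance is numerically zero are skipped
    with a warning.
    """
    Y = np.asarray(Y, dtype=np.float64)
    if Y.shape[0] < 2:
        raise ValueError("population kurtosis needs K >= 2 neurons")
    d = Y - Y.mean(axis=0)
    v = (d**2).mean(axis=0)
    valid = v >= 1e-12
    if not valid.all():
        warnings.warn(f"skipping {int((~valid).sum())} time point(s) with zero population variance")
    if not valid.any():
        return 0.0
    mu4 = (d**4).mean(axis=0)
    return float(np.mean(mu4[valid] / v[valid] ** 2))


def kurtosis_gradient(B: np.ndarray, Z) -> np.ndarray:
    """Analytic gradient of the population-kurtosis objective w.r.t. B."""
    Z = _as_matrix(Z)
    Y = B.T @ Z
    K = Y.shape[0]
    if K < 2:
        raise ValueError("population kurtosis needs K >= 2 neurons")
    d = Y - Y.mean(axis=0)
    v = (d**2).mean(axis=0)
    valid = v >= 1e-12
    n_valid = int(valid.sum())
    if n_valid == 0:
        return np.zeros_like(B)
    mu4 = (d**4).mean(axis=0)
    d3 = d**3
    # d(mu4/v^2)/dy_i = (4/K)(d_i^3 - <d^3>)/v^2 - (4/K) mu4 d_i / v^3
    G = (4.0 / K) * ((d3 - d3.mean(axis=0)) / np.where(valid, v, 1.0) ** 2
                     - mu4 * d / np.where(valid, v, 1.0) ** 3)
    G[:, ~valid] = 0.0
    G /= n_valid
    return Z @ G.T


def procrustes_project(A: np.ndarray) -> np.ndarray:
    """Nearest matrix with orthonormal columns: A (A^T A)^{-1/2} = U V^T.

    Computed from the thin SVD A = U S V^T; minimizes the Frobenius distance
    to A over the Stiefel manifold.  Rank-deficient input is an error.
    """
    A = np.asarray(A, dtype=np.float64)
    U, S, Vt = np.linalg.svd(A, full_matrices=False)
    tol = max(A.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    rank = int((S > tol).sum())
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError(
            f"input is rank-deficient (rank {rank} < {A.shape[1]} columns)"
        )
    return U @ Vt


_OBJECTIVES = {
    "sustained": (sustained_objective, sustained_gradient),
    "sparse": (lambda Y, cfg=None: kurtosis_objective(Y), lambda B, Z, cfg=None: kurtosis_gradient(B, Z)),
}


def fit_ensemble(
    data,
    K: int = 400,
    objective: ObjectiveConfig | None = None,
    mode: str = "response",
    mu: float = 1.0,
    max_iter: int = 30,
    tol: float = 1e-4,
    seed: int = 0,
    whitening: WhiteningModel | None = None,
    max_halvings: int = 50,
    patch_shape: tuple | None = None,
):
    """Rosen projected-gradient ascent of an objective over orthonormal ensembles.

    ``data`` is whitened (M x T) for ``mode='response'`` or raw preprocessed
    patches (D x T) for ``mode='shape'``.  The ensemble is initialized from
    seeded zero-mean unit-variance Gaussian noise projected to orthonormal
    columns; each outer iteration takes B <- project(B + mu 2^{-k} grad),
    halving the step (k += 1, reset per iteration) while the candidate would
    decrease the objective.  Learning stops when the relative objective
    change falls below ``tol``, after ``max_iter`` iterations, or when step
    halving is exhausted.  For response mode with a ``whitening`` model, the
    raw-coordinate STRFs are attached to the returned ensemble.

    Returns ``(STRFEnsemble, TraceRecord)``.
    """
    if mode not in ("response", "shape"):
        raise ValueError("mode must be 'response' or 'shape'")
    objective = objective or ObjectiveConfig()
    X = _as_matrix(data)
    dim, T = X.shape
    if K > dim:
        raise ValueError(f"K={K} exceeds data dimension {dim}")
    obj_fn, grad_fn = _OBJECTIVES[objective.kind]

    rng = np.random.default_rng(seed)
    B = procrustes_project(rng.standard_normal((dim, K)))
    psi = obj_fn(B.T @ X, objective)
    trace = TraceRecord()
    trace.objectives.append(psi)
    trace.residuals.append(float(np.linalg.norm(B.T @ B - np.eye(K))))
    trace.halvings.append(0)

    for _ in range(max_iter):
        g = grad_fn(B, X, objective)
        k = 0
        cand, psi_c = None, None
        while True:
            cand = procrustes_project(B + mu * 2.0 ** (-k) * g)
            psi_c = obj_fn(cand.T @ X, objective)
            if psi_c >= psi:
                break
            k += 1
            if k > max_halvings:
                cand = None
                break
        if cand is None:
            trace.stop_reason = "step_halving_exhausted"
            break
        rel = (psi_c - psi) / max(abs(psi), np.finfo(float).tiny)
        B, psi = cand, psi_c
        trace.objectives.append(psi)
        trace.residuals.append(float(np.linalg.norm(B.T @ B - np.eye(K))))
        trace.halvings.append(k)
        if rel < tol:
            trace.stop_reason = "converged"
            break
    if not trace.stop_reason:
        trace.stop_reason = "max_iter"

    if patch_shape is None and isinstance(data, PatchMatrix):
        patch_shape = data.patch_shape
    strfs = None
    if mode == "response" and whitening is not None:
        strfs = unwhiten_filters(B, whitening)
    ens = STRFEnsemble(
        filters=B,
        coordinate_space="whitened" if mode == "response" else "raw",
        constraint_mode=mode,
        objective=objective,
        seed=seed,
        patch_shape=patch_shape,
        strfs=strfs,
    )
    return ens, trace


def per_filter_contribution(ensemble: STRFEnsemble, Y: np.ndarray, config: ObjectiveConfig | None = None):
    """Each filter's additive share of the sustained objective, plus descending order.

    The sustained objective is a sum of K independent per-filter terms, so the
    emergent STRFs can be sorted by contribution; the population-kurtosis
    objective does not decompose this way and is unsupported.

    Returns ``(scores, order)`` with ``scores.sum() == Psi_s``.
    """
    config = config or ensemble.objective
    if config.kind != "sustained":
        raise ValueError("per-filter contributions are only defined for the sustained objective")
    scores = _sustained_per_filter(Y, config)
    return scores, np.argsort(-scores, kind="stable")
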