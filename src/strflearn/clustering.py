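"""Grouping canonical classes of STRFs.

Pairwise STRF similarity is the maximum absolute value of the normalized 2D
cross-correlation over all time-frequency shifts (patches pre-normalized to
unit Frobenius norm, so similarities lie in [0, 1] and sign — excitatory vs
inhibitory — is ignored).  The similarity matrix feeds normalized spectral
clustering (eigenvectors of D^{-1/2} W D^{-1/2}, row-normalized, k-means),
after which clusters dominated by *noisy* STRFs (high mean separability
index) and by *localized* STRFs (high mean compactness) are each merged into
a single class.  Class-distribution entropy summarizes ensemble diversity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats
from sklearn.cluster import KMeans

__all__ = [
    "SimilarityMatrix",
    "ClusterResult",
    "strf_similarity",
    "similarity_matrix",
    "spectral_cluster",
    "merge_clusters",
    "class_entropy",
]

logger = logging.getLogger(__name__)


@dataclass
class SimilarityMatrix:
    W: np.ndarray

    def __post_init__(self):
        W = np.asarray(self.W, dtype=np.float64)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(W, W.T, atol=1e-10):
            raise ValueError("similarity matrix must be symmetric")
        self.W = W

    @property
    def n(self) -> int:
        return self.W.shape[0]

    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def normalized_affinity(self) -> np.ndarray:
        d = self.degrees()
        if np.any(d <= 0):
            raise ValueError("isolated node with zero degree")
        dm12 = 1.0 / np.sqrt(d)
        return dm12[:, None] * self.W * dm12[None, :]


@dataclass
class ClusterResult:
    initial_labels: np.ndarray
    merged_labels: np.ndarray
    cluster_mean_spi: dict
    cluster_mean_compactness: dict
    seed: int


def strf_similarity(patch_i: np.ndarray, patch_j: np.ndarray) -> float:
    """Max over all 2D shifts of |normalized cross-correlation| of two patches.

    Both patches are scaled to unit Frobenius norm first, so the value lies
    in [0, 1] (Cauchy-Schwarz) and is invariant to sign flips of either
    patch.
    """
    a = np.asarray(patch_i, dtype=np.float64)
    b = np.asarray(patch_j, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("patches must share a shape")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero patch has undefined similarity")
    xc = signal.correlate(a / na, b / nb, mode="full", method="fft")
    return float(min(np.abs(xc).max(), 1.0))


def similarity_matrix(patches) -> SimilarityMatrix:
    """W[i, j] = strf_similarity(patch_i, patch_j), with unit diagonal."""
    patches = [np.asarray(p, dtype=np.float64) for p in patches]
    n = len(patches)
    if n < 2:
        raise ValueError("need at least 2 patches")
    W = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                W[i, j] = W[j, i] = strf_similarity(patches[i], patches[j])
            except ValueError as e:
                raise ValueError(f"similarity failed for pair ({i}, {j}): {e}") from e
    return SimilarityMatrix(W=W)


def spectral_cluster(W, k: int = 12, seed: int = 0, n_restarts: int = 20) -> np.ndarray:
    """Normalized spectral clustering (Ng-Jordan-Weiss style).

    Eigenvectors of the normalized affinity D^{-1/2} W D^{-1/2} for the k
    largest eigenvalues are row-normalized and clustered with seeded k-means
    (best of ``n_restarts`` by inertia).
    """
    if not isinstance(W, SimilarityMatrix):
        W = SimilarityMatrix(W=np.asarray(W))
    n = W.n
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == n:
        return np.arange(n)
    A = W.normalized_affinity()
    evals, evecs = np.linalg.eigh(A)
    U = evecs[:, -k:]  # k largest eigenvalues
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    U = U / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    return km.fit_predict(U)


def _pooled_means(labels, values):
    """Per-cluster mean of a metric, ignoring NaNs."""
    out = {}
    for c in np.unique(labels):
        v = np.asarray(values)[labels == c]
        v = v[np.isfinite(v)]
        out[int(c)] = float(v.mean()) if v.size else float("nan")
    return out


def _greedy_merge(labels, values, threshold):
    """Absorb clusters, ranked by mean metric descending, while the next
    cluster's own mean exceeds the threshold; returns the merged cluster ids
    (empty or singleton -> no-op)."""
    means = _pooled_means(labels, values)
    ranked = sorted(means, key=lambda c: -means[c])
    group = [c for c in ranked if np.isfinite(means[c]) and means[c] > threshold]
    # Keep only the maximal prefix of the ranking (means are sorted, so any
    # qualifying cluster is in the prefix already).
    if len(group) < 2:
        logger.info("merge is a no-op (%d cluster(s) above threshold %.3g)", len(group), threshold)
        return []
    return group


def merge_clusters(
    initial_labels,
    spi,
    compactness,
    spi_threshold: float = 0.5,
    q_threshold: float = 0.69,
) -> np.ndarray:
    """Merge noisy and localized cluster groups into single classes.

    Clusters are ranked by mean separability index (SPI); the top-ranked
    clusters whose mean SPI exceeds ``spi_threshold`` are pooled into one
    *noisy* class (their pooled mean then also exceeds the threshold).  Among
    the remaining clusters, those whose mean compactness exceeds
    ``q_threshold`` are pooled into one *localized* class.  Labels are
    relabeled contiguously.  With 12 initial clusters, 3 noisy and 2
    localized, this yields the canonical 9 classes.
    """
    labels = np.asarray(initial_labels).copy()
    spi = np.asarray(spi, dtype=np.float64)
    q = np.asarray(compactness, dtype=np.float64)
    if labels.shape != spi.shape or labels.shape != q.shape:
        raise ValueError("metrics must be available for every item")

    noisy_group = _greedy_merge(labels, spi, spi_threshold)
    if noisy_group:
        target = min(noisy_group)
        labels[np.isin(labels, noisy_group)] = target

    mask_rest = ~np.isin(labels, noisy_group) if noisy_group else np.ones_like(labels, dtype=bool)
    sub_labels = labels[mask_rest]
    sub_q = q[mask_rest]
    loc_group = _greedy_merge(sub_labels, sub_q, q_threshold) if sub_labels.size else []
    if loc_group:
        target = min(loc_group)
        labels[np.isin(labels, loc_group) & mask_rest] = target

    # contiguous relabeling preserving sorted original ids
    uniq = np.unique(labels)
    remap = {c: i for i, c in enumerate(uniq)}
    return np.array([remap[c] for c in labels])


def class_entropy(labels) -> float:
    """Shannon entropy (bits) of the empirical class distribution."""
    labels = np.asarray(labels)
    if labels.size < 1:
        raise ValueError("need at least one label")
    _, counts = np.unique(labels, return_counts=True)
    return float(stats.entropy(counts, base=2))
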