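"""Visual vocabulary construction by K-means clustering.

The codebook is the set of K cluster centers fitted to training
descriptors by Lloyd's algorithm: assign each descriptor to its closest
center, recompute each center as the mean of its members, repeat until no
assignment changes. The in-loop objective (total squared distance to
assigned centers, the inertia) is asserted non-increasing every iteration,
and an emptied cluster is re-seeded with the point farthest from its
current center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Codebook", "fit_kmeans", "assign_nearest"]

_CHUNK = 8192  # rows per distance block, keeps the N x K matrix bounded


@dataclass
class Codebook:
    centers: np.ndarray  # (K, d)
    K: int
    seed: int
    n_iter: int
    inertia: float

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not np.all(np.isfinite(self.centers)):
            raise ValueError("non-finite center")


def _sq_dists(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances, clipped at 0 against rounding."""
    d = (X * X).sum(1)[:, None] + (C * C).sum(1)[None, :] - 2.0 * X @ C.T
    return np.maximum(d, 0.0)


def _assign(X: np.ndarray, C: np.ndarray):
    """(labels, squared distance to own center), chunked over rows."""
    n = X.shape[0]
    labels = np.empty(n, dtype=np.intp)
    dmin = np.empty(n)
    for i in range(0, n, _CHUNK):
        d = _sq_dists(X[i:i + _CHUNK], C)
        labels[i:i + _CHUNK] = d.argmin(1)
        dmin[i:i + _CHUNK] = d[np.arange(d.shape[0]), labels[i:i + _CHUNK]]
    return labels, dmin


def _kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first center uniform, the rest D**2-sampled."""
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = _sq_dists(X, centers[:1]).ravel()
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = X[rng.integers(n)]
        else:
            centers[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, _sq_dists(X, centers[k:k + 1]).ravel())
    return centers


def fit_kmeans(
    descriptors: np.ndarray,
    K: int = 2000,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-4,
    init: str = "kmeans++",
) -> Codebook:
    """Fit the K-entry vocabulary by Lloyd iterations.

    Stops at an assignment fixpoint, when the relative inertia change drops
    below ``tol``, or after ``max_iter`` iterations. ``init`` is
    'kmeans++' (default) or 'random' (K distinct training points). Fixed
    ``seed`` gives a bitwise-reproducible codebook.
    """
    X = np.ascontiguousarray(descriptors, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("descriptors must be a 2-D array")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite descriptor")
    n = X.shape[0]
    if n < K:
        raise ValueError(
            f"need at least K={K} descriptors, got {n}: reduce K or supply "
            "more training patches")
    rng = np.random.default_rng(seed)
    if init == "kmeans++":
        C = _kmeanspp(X, K, rng)
    elif init == "random":
        C = X[rng.choice(n, size=K, replace=False)].copy()
    else:
        raise ValueError("init must be 'kmeans++' or 'random'")

    labels, dmin = _assign(X, C)
    inertia = float(dmin.sum())
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        for k in range(K):
            members = labels == k
            if members.any():
                C[k] = X[members].mean(0)
            else:
                C[k] = X[np.argmax(dmin)]  # farthest point re-seeds the cluster
                dmin[np.argmax(dmin)] = 0.0
        new_labels, dmin = _assign(X, C)
        new_inertia = float(dmin.sum())
        assert new_inertia <= inertia * (1 + 1e-12) + 1e-12, \
            "k-means objective increased"
        converged = np.array_equal(new_labels, labels)
        small_change = inertia > 0 and (inertia - new_inertia) / inertia < tol
        labels, inertia = new_labels, new_inertia
        if converged or small_change or inertia == 0.0:
            break
    return Codebook(centers=C, K=K, seed=seed, n_iter=n_iter, inertia=inertia)


def assign_nearest(codebook: Codebook, descriptor: np.ndarray) -> int:
    """Index of the Euclidean-nearest codeword (lowest index on ties)."""
    x = np.asarray(descriptor, dtype=np.float64).ravel()
    if x.shape[0] != codebook.centers.shape[1]:
        raise ValueError("descriptor width does not match codebook")
    return int(_sq_dists(x[None, :], codebook.centers).argmin())
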