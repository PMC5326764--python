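"""Locality-constrained linear coding (LLC) and hard vector quantization.

LLC represents a descriptor x as an affine combination (weights summing to
1) of its k nearest codewords B, minimizing the local reconstruction error

    min_c ||x - B c||^2 + lambda * tr(Z Z^T) * ||c||^2   s.t.  sum(c) = 1

where Z = B - x are the shifted local bases; the trace-scaled ridge keeps
the local Gram system well-conditioned (e.g. when two selected codewords
coincide). The closed form solves (Z Z^T + reg I) w = 1 and normalizes w to
unit sum. Hard assignment (the vector-quantization baseline of classic
bag-of-words) is the one-hot code at the nearest codeword.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codebook import Codebook, assign_nearest, _sq_dists

__all__ = ["Code", "encode_llc", "encode_hard", "encode_batch"]


@dataclass
class Code:
    """Sparse code: active codeword indices with matching weights."""

    indices: np.ndarray
    weights: np.ndarray
    K: int

    def dense(self) -> np.ndarray:
        v = np.zeros(self.K)
        v[self.indices] = self.weights
        return v


def _llc_weights(x: np.ndarray, B: np.ndarray, lam: float) -> np.ndarray:
    Z = B - x
    G = Z @ Z.T
    tr = np.trace(G)
    reg = lam * tr if tr > 0 else lam
    G = G + reg * np.eye(B.shape[0])
    w = np.linalg.solve(G, np.ones(B.shape[0]))
    return w / w.sum()


def encode_llc(
    codebook: Codebook, descriptor: np.ndarray, k_nn: int = 5, lam: float = 1e-4
) -> Code:
    """LLC code of one descriptor over its ``k_nn`` nearest codewords."""
    x = np.asarray(descriptor, dtype=np.float64).ravel()
    if k_nn > codebook.K:
        raise ValueError("k_nn cannot exceed the codebook size")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite descriptor")
    d2 = _sq_dists(x[None, :], codebook.centers).ravel()
    nn = np.argsort(d2, kind="stable")[:k_nn]
    w = _llc_weights(x, codebook.centers[nn], lam)
    return Code(indices=nn, weights=w, K=codebook.K)


def encode_hard(codebook: Codebook, descriptor: np.ndarray) -> Code:
    """One-hot code at the nearest codeword (lowest index on ties)."""
    i = assign_nearest(codebook, descriptor)
    return Code(indices=np.array([i]), weights=np.array([1.0]), K=codebook.K)


def encode_batch(
    codebook: Codebook,
    descriptors: np.ndarray,
    method: str = "llc",
    k_nn: int = 5,
    lam: float = 1e-4,
) -> list:
    """Encode a descriptor matrix row by row; the batched k-NN search and
    stacked k x k solves make this the fast path used by the pipeline."""
    X = np.asarray(descriptors, dtype=np.float64)
    if X.shape[0] == 0:
        return []
    if method == "hard":
        d2 = _sq_dists(X, codebook.centers)
        idx = d2.argmin(1)
        return [Code(indices=np.array([i]), weights=np.array([1.0]), K=codebook.K)
                for i in idx]
    if method != "llc":
        raise ValueError("method must be 'llc' or 'hard'")
    k = min(k_nn, codebook.K)
    d2 = _sq_dists(X, codebook.centers)
    part = np.argpartition(d2, k - 1, axis=1)[:, :k]
    # deterministic order: sort the selected neighbors by (distance, index)
    rows = np.arange(X.shape[0])[:, None]
    order = np.lexsort((part, d2[rows, part]), axis=1)
    nn = part[rows, order]
    Z = codebook.centers[nn] - X[:, None, :]  # (N, k, d)
    G = Z @ Z.transpose(0, 2, 1)
    tr = np.trace(G, axis1=1, axis2=2)
    reg = np.where(tr > 0, lam * tr, lam)
    G = G + reg[:, None, None] * np.eye(k)
    W = np.linalg.solve(G, np.ones((X.shape[0], k, 1)))[:, :, 0]
    W = W / W.sum(1, keepdims=True)
    return [Code(indices=nn[i], weights=W[i], K=codebook.K) for i in rows.ravel()]
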