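"""Decorrelation-stretch color enhancement.

Young wheat ears are nearly the same color as the surrounding leaves; the
three RGB channels of a canopy image are strongly correlated, so the
ear/leaf difference lives in a low-variance direction of color space.
Decorrelation stretching removes the inter-channel correlation by PCA
whitening and re-stretches every principal direction to a common standard
deviation, exaggerating exactly those subtle color differences.

The transform, for pixel color x with channel mean mu, eigenvectors R and
eigenvalues v of the channel covariance:

    c = R diag(1/sqrt(v_i + delta)) R^T (x - mu) * target_sd + recenter

so that (before clipping to the 8-bit range) the output channel covariance
is target_sd**2 * I whenever all eigenvalues are well above the guard
delta = 1e-6 * max(v).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChannelStats", "channel_stats", "decorrelation_stretch", "contrast_stretch"]

# Degenerate-eigenvalue guard, relative to the largest eigenvalue. Small
# enough that the whitened covariance of any sanely conditioned image
# matches target_sd**2 * I to better than 1e-6 relative error, yet it still
# keeps a perfectly flat channel from dividing by zero.
_EIG_GUARD_REL = 1e-12


@dataclass
class ChannelStats:
    """Per-channel first/second moments and the eigendecomposition of the
    3x3 channel covariance (eigenvalues descending, eigenvectors as columns,
    sign fixed so each column's largest-magnitude entry is positive)."""

    means: np.ndarray
    covariance: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def __post_init__(self):
        tr = float(np.trace(self.covariance))
        if np.any(self.eigenvalues < -1e-9 * max(tr, 1.0)):
            raise ValueError("covariance is not positive semi-definite")
        gram = self.eigenvectors.T @ self.eigenvectors
        if not np.allclose(gram, np.eye(3), atol=1e-8):
            raise ValueError("eigenvectors are not orthonormal")


def _validate(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(f"expected HxWx3 image, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("empty image")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def channel_stats(image: np.ndarray) -> ChannelStats:
    """Channel means, population covariance and its eigendecomposition.

    The covariance is computed over all pixels with denominator n
    (population form). Eigenpairs are sorted by descending eigenvalue and
    each eigenvector's sign is fixed so that its largest-magnitude entry is
    positive (first index on ties), making the decomposition deterministic.
    """
    img = _validate(image)
    flat = img.reshape(-1, 3)
    means = flat.mean(axis=0)
    centered = flat - means
    cov = centered.T @ centered / flat.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    for j in range(3):
        col = evecs[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax takes first index on ties
        if col[i] < 0:
            evecs[:, j] = -col
    return ChannelStats(means=means, covariance=cov, eigenvalues=evals, eigenvectors=evecs)


def decorrelation_stretch(
    image: np.ndarray,
    target_sd: float = 50.0,
    recenter: float = 127.5,
    matrix: str = "covariance",
    clip: bool = True,
) -> np.ndarray:
    """Whiten the channel covariance and re-stretch to a common contrast.

    Parameters
    ----------
    image : HxWx3 array in [0, 255].
    target_sd : standard deviation of every output channel before clipping.
    recenter : output mid-level; 127.5 centers the 8-bit range.
    matrix : 'covariance' (default) or 'correlation' — whether eigenpairs
        come from the covariance or the correlation matrix of the channels.
    clip : clamp the result to [0, 255]; disable to inspect the raw
        whitened values (used by the whitening tests).

    A degenerate eigenvalue is guarded by delta = 1e-12 * max(v); an
    all-constant image maps to an image filled with ``recenter``.
    """
    if target_sd <= 0:
        raise ValueError("target_sd must be positive")
    img = _validate(image)
    stats = channel_stats(img)
    flat = img.reshape(-1, 3)
    centered = flat - stats.means

    if matrix == "correlation":
        sd = np.sqrt(np.clip(np.diag(stats.covariance), 0.0, None))
        sd_safe = np.where(sd > 0, sd, 1.0)
        scaled = centered / sd_safe
        corr = scaled.T @ scaled / flat.shape[0]
        evals, evecs = np.linalg.eigh(corr)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        for j in range(3):
            col = evecs[:, j]
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                evecs[:, j] = -col
        centered = scaled
    elif matrix == "covariance":
        evals, evecs = stats.eigenvalues, stats.eigenvectors
    else:
        raise ValueError("matrix must be 'covariance' or 'correlation'")

    vmax = float(evals.max())
    if vmax <= 0.0:
        return np.full_like(img, recenter)
    delta = _EIG_GUARD_REL * vmax
    # c = R D R^T (x - mu), D = diag(1/sqrt(v + delta))
    transform = evecs @ np.diag(1.0 / np.sqrt(evals + delta)) @ evecs.T
    out = centered @ transform.T * target_sd + recenter
    out = out.reshape(img.shape)
    return np.clip(out, 0.0, 255.0) if clip else out


def contrast_stretch(
    image: np.ndarray, low_pct: float = 1.0, high_pct: float = 99.0
) -> np.ndarray:
    """Per-channel linear percentile stretch.

    Maps the ``low_pct`` percentile to 0 and the ``high_pct`` percentile to
    255, clipping outside; a channel with zero dynamic range between the two
    percentiles passes through unchanged.
    """
    if not (0 <= low_pct < high_pct <= 100):
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    img = _validate(image)
    out = img.copy()
    for c in range(3):
        lo, hi = np.percentile(img[..., c], [low_pct, high_pct])
        if hi > lo:
            out[..., c] = np.clip((img[..., c] - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
    return out
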