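"""Spatial-pyramid pooling of per-descriptor codes.

Plain bag-of-words discards where in the image the features lie; the
spatial pyramid restores coarse layout by pooling separate histograms over
nested grids (1x1, 2x2, 4x4 for 3 levels), weighting each level and
concatenating the blocks. With a K-word vocabulary and 3 levels the image
representation has (1 + 4 + 16) * K = 21K entries — 42,000 at K = 2000.

Absolute code weights are pooled so the result keeps histogram semantics
(non-negative), as the Hellinger feature map downstream requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpmVector", "pool_spm", "spm_region_count"]

DEFAULT_LEVEL_WEIGHTS = (0.25, 0.25, 0.5)


@dataclass
class SpmVector:
    """Pooled image representation.

    Layout: level-0 block (1*K), then level-1 blocks (4*K, sub-regions in
    row-major order), then level-2 blocks (16*K, row-major). ``empty``
    flags an image with no codes (all-zero vector).
    """

    values: np.ndarray
    K: int
    levels: int
    normalization: str = "l1"
    empty: bool = False

    def __len__(self) -> int:
        return self.values.shape[0]


def spm_region_count(levels: int = 3) -> int:
    """Total sub-regions over ``levels`` grid levels: sum of 4**l."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    return sum(4 ** l for l in range(levels))


def pool_spm(
    codes: list,
    positions,
    image_size: tuple,
    K: int,
    mode: str = "sum",
    levels: int = 3,
    level_weights=None,
) -> SpmVector:
    """Pool codes over the spatial pyramid into one image vector.

    A keypoint at (x, y) in a g x g grid falls in cell
    (floor(g*x/W), floor(g*y/H)), half-open, with points exactly on the
    right/bottom edge clamped to the last cell. Per-cell histograms
    accumulate |code weight| per word by ``mode`` 'sum' or 'max'; each
    level's block is scaled by its level weight and the concatenation is
    L1-normalized.
    """
    if mode not in ("sum", "max"):
        raise ValueError("mode must be 'sum' or 'max'")
    if level_weights is None:
        level_weights = DEFAULT_LEVEL_WEIGHTS[:levels] if levels <= 3 else \
            [1.0 / levels] * levels
    level_weights = np.asarray(level_weights, dtype=np.float64)
    if level_weights.shape[0] != levels:
        raise ValueError("need one weight per level")
    W, H = image_size
    pos = np.asarray(positions, dtype=np.float64).reshape(-1, 2)
    if len(codes) != pos.shape[0]:
        raise ValueError("codes and positions length mismatch")
    total = spm_region_count(levels) * K
    if len(codes) == 0:
        return SpmVector(values=np.zeros(total), K=K, levels=levels, empty=True)
    if np.any(pos[:, 0] < 0) or np.any(pos[:, 0] > W) or \
       np.any(pos[:, 1] < 0) or np.any(pos[:, 1] > H):
        raise ValueError("keypoint position outside the image")

    blocks = []
    for l in range(levels):
        g = 2 ** l
        cells = np.zeros((g * g, K))
        cx = np.minimum((g * pos[:, 0] / W).astype(int), g - 1)
        cy = np.minimum((g * pos[:, 1] / H).astype(int), g - 1)
        cell_idx = cy * g + cx
        for code, ci in zip(codes, cell_idx):
            wabs = np.abs(code.weights)
            if mode == "sum":
                np.add.at(cells[ci], code.indices, wabs)
            else:
                np.maximum.at(cells[ci], code.indices, wabs)
        blocks.append(level_weights[l] * cells.ravel())
    vec = np.concatenate(blocks)
    s = vec.sum()
    if s > 0:
        vec = vec / s
    return SpmVector(values=vec, K=K, levels=levels, empty=False)
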