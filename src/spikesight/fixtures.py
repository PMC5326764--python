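"""Seeded synthetic two-class imagery for exercising the pipeline.

Real field canopies are not required to test the machinery: the generator
emits procedural textures that exercise every operator — multi-scale
elongated blobs with a high-frequency chevron (spikelet-like) pattern for
the "ear" class, low-frequency oriented stripes with smooth mottling
(leaf-like) for the "background" class, strongly correlated RGB channels so
decorrelation stretching has something to remove, plus controllable
illumination gain/offset and occlusion. The two classes differ in texture
statistics by construction, so a classifier failure signals a pipeline bug
rather than data ambiguity. Everything is a pure function of the spec's
seed; per-image sub-seeds are derived by counter, never from global state.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .image import save_image

__all__ = ["FixtureSpec", "make_patch", "make_canvas", "make_dataset",
           "ILLUMINATION_PROBE"]

#: the standard illumination-robustness probe: a strong, channel-asymmetric
#: contrast compression (overcast-like flattening) applied to test copies
#: when measuring how much decorrelation stretching buys
ILLUMINATION_PROBE = {"gain": (0.4, 0.33, 0.5), "offset": (60.0, 60.0, 40.0)}

#: mean RGB of the two texture classes (wheat-green tones, deliberately
#: close so that texture, not raw color, carries the class signal)
_BASE_COLOR = {"ear": (120.0, 138.0, 78.0), "background": (104.0, 132.0, 74.0)}
_CONTRAST = 55.0  # intensity amplitude of the texture around the base color


@dataclass
class FixtureSpec:
    """Parameters of one synthetic patch; ``seed`` fully determines it."""

    seed: int = 0
    size: int = 64
    label: str = "ear"
    # ear-class texture
    blob_count: int = 4
    elongation: float = 3.0
    orientation_jitter: float = 0.5  # rad around vertical
    awn_prob: float = 0.5
    chevron_wavelength: float = 5.0  # px, spikelet-like high-frequency texture
    # background-class texture
    stripe_wavelength: float = 18.0  # px, leaf-like low-frequency stripes
    stripe_orientation: float | None = None  # rad; None -> random
    # shared color / nuisance model
    channel_correlation: float = 0.95
    gain: tuple = (1.0, 1.0, 1.0)
    offset: tuple = (0.0, 0.0, 0.0)
    occlusion: float = 0.0

    def __post_init__(self):
        if self.size < 32:
            raise ValueError("patch size must be >= 32 px")
        if self.label not in ("ear", "background"):
            raise ValueError("label must be 'ear' or 'background'")
        if not (0.0 <= self.occlusion <= 1.0):
            raise ValueError("occlusion must be in [0, 1]")
        if not (0.0 <= self.channel_correlation <= 1.0):
            raise ValueError("channel_correlation must be in [0, 1]")


def _standardize(a: np.ndarray) -> np.ndarray:
    s = a.std()
    return (a - a.mean()) / s if s > 0 else np.zeros_like(a)


def _smooth_noise(rng, shape, sigma):
    return ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")


def _ear_texture(rng, n: int, spec: FixtureSpec) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    tex = 0.3 * _smooth_noise(rng, (n, n), 4.0)
    for _ in range(spec.blob_count):
        cx, cy = rng.uniform(0.15 * n, 0.85 * n, size=2)
        theta = np.pi / 2 + rng.uniform(-spec.orientation_jitter,
                                        spec.orientation_jitter)
        length = rng.uniform(0.28, 0.42) * n
        width = length / spec.elongation
        u = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
        v = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
        mask = np.exp(-(u ** 2 / (2 * (length / 2) ** 2)
                        + v ** 2 / (2 * (width / 2) ** 2)))
        # spikelet grid: alternating bright bumps along the ear axis, offset
        # rows on either flank (chevron-like packing)
        phase = rng.uniform(0, 2 * np.pi)
        lam = spec.chevron_wavelength
        wave = (np.sin(2 * np.pi * (u + np.abs(v) * 0.7) / lam + phase)
                * np.cos(2 * np.pi * v / (1.6 * lam)))
        tex += mask * (0.8 + 1.3 * wave)
        if rng.uniform() < spec.awn_prob:
            # thin bright streak beyond the blob tip
            au = u - length / 2
            awn = np.exp(-(au ** 2 / (2 * (length / 3) ** 2)
                           + v ** 2 / (2 * 1.2 ** 2)))
            tex += 0.9 * awn * (au > 0)
    return tex


def _background_texture(rng, n: int, spec: FixtureSpec) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    theta = (rng.uniform(0, np.pi) if spec.stripe_orientation is None
             else spec.stripe_orientation)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    phase = rng.uniform(0, 2 * np.pi)
    stripes = np.sin(2 * np.pi * u / spec.stripe_wavelength + phase)
    bend = 2.5 * _smooth_noise(rng, (n, n), 8.0)  # gently curved leaves
    stripes = np.sin(2 * np.pi * (u + bend) / spec.stripe_wavelength + phase)
    mottle = 0.55 * _smooth_noise(rng, (n, n), 3.0)
    return stripes + mottle


def make_patch(spec: FixtureSpec):
    """Render one patch; returns (HxWx3 raster in [0, 255], label).

    The three channels share the class texture through a common component
    weighted so their pairwise correlation equals
    ``spec.channel_correlation``; illumination gain/offset and an optional
    dark occluding blob are applied last. Same spec -> bitwise-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    if spec.label == "ear":
        tex = _ear_texture(rng, n, spec)
    else:
        tex = _background_texture(rng, n, spec)
    z = _standardize(tex)
    rho = spec.channel_correlation
    base = _BASE_COLOR[spec.label]
    img = np.empty((n, n, 3))
    for c in range(3):
        e = _standardize(_smooth_noise(rng, (n, n), 2.0))
        img[..., c] = base[c] + _CONTRAST * (np.sqrt(rho) * z
                                             + np.sqrt(1 - rho) * e)
    if spec.occlusion > 0:
        # one dark elliptical occluder covering ~occlusion of the area
        area = spec.occlusion * n * n
        a = np.sqrt(area / np.pi) * rng.uniform(1.0, 1.6)
        b = area / np.pi / a
        cy, cx = rng.uniform(0.2 * n, 0.8 * n, size=2)
        th = rng.uniform(0, np.pi)
        yy, xx = np.mgrid[0:n, 0:n].astype(float)
        u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
        v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        shade = 28.0 + 6.0 * _smooth_noise(rng, (n, n), 6.0)
        for c in range(3):
            ch = img[..., c]
            ch[inside] = shade[inside] * (0.8 + 0.1 * c)
    for c in range(3):
        img[..., c] = img[..., c] * spec.gain[c] + spec.offset[c]
    return np.clip(img, 0.0, 255.0), spec.label


def make_canvas(spec: FixtureSpec, scale: int = 2):
    """A larger composite "canopy" scene: the class texture rendered at
    ``scale`` times the patch size with proportionally more blobs, for
    patch-train / full-image-test experiments."""
    big = replace(spec, size=spec.size * scale,
                  blob_count=spec.blob_count * scale * scale)
    return make_patch(big)


def _nuisance(rng, illum_range=0.2, offset_range=10.0, occl_prob=0.3,
              occl_max=0.25):
    g0 = rng.uniform(1 - illum_range, 1 + illum_range)
    gain = tuple(g0 * rng.uniform(0.95, 1.05) for _ in range(3))
    offset = tuple(rng.uniform(-offset_range, offset_range) for _ in range(3))
    occ = rng.uniform(0.05, occl_max) if rng.uniform() < occl_prob else 0.0
    return gain, offset, occ


def make_dataset(
    n_per_class: int,
    seed: int,
    out_dir,
    size: int = 64,
    train_frac: float = 0.8,
    canvas_test: bool = False,
    **spec_overrides,
):
    """Write a directory-per-class image dataset with an 80/20 split.

    Layout: ``out_dir/{train,test}/{ear,background}/NNN.png`` plus a
    ``manifest.tsv`` recording every patch's generation parameters.
    Each image's sub-seed is ``seed * 100000 + counter``, so different
    master seeds give disjoint pixel content with identical layout.
    Training images carry mild illumination/occlusion variation (the
    conditions a field dataset would show); with ``canvas_test`` the test
    split holds larger composite scenes instead of patches.

    Returns a :class:`spikesight.pipeline.Dataset` over ``out_dir``.
    """
    from .pipeline import Dataset  # local import to avoid a cycle

    if n_per_class < 2:
        raise ValueError("need at least 2 images per class")
    out = Path(out_dir)
    rng = np.random.default_rng(seed)
    n_train = int(round(n_per_class * train_frac))
    rows = []
    counter = 0
    for label in ("ear", "background"):
        for i in range(n_per_class):
            split = "train" if i < n_train else "test"
            sub_seed = seed * 100000 + counter
            counter += 1
            gain, offset, occ = _nuisance(rng)
            kwargs = {"gain": gain, "offset": offset, "occlusion": occ}
            kwargs.update(spec_overrides)  # explicit overrides win
            spec = FixtureSpec(seed=sub_seed, size=size, label=label, **kwargs)
            if split == "test" and canvas_test:
                img, _ = make_canvas(spec)
            else:
                img, _ = make_patch(spec)
            d = out / split / label
            d.mkdir(parents=True, exist_ok=True)
            path = d / f"{i:03d}.png"
            save_image(path, img)
            rows.append({
                "path": str(path.relative_to(out)), "label": label,
                "split": split, "seed": sub_seed,
                "gain": ",".join(f"{g:.4f}" for g in gain),
                "offset": ",".join(f"{o:.2f}" for o in offset),
                "occlusion": f"{occ:.3f}",
            })
    with open(out / "manifest.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    return Dataset.from_directory(out)
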