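"""Scale-invariant feature transform (SIFT) keypoints and descriptors.

The four classical stages on a single-channel image:

1. a Gaussian scale-space pyramid (octaves of progressively blurred images,
   adjacent levels separated by the constant factor k = 2**(1/s));
2. difference-of-Gaussians (DoG) levels by simple image subtraction, whose
   3x3x3 strict extrema (8 spatial + 2x9 across-scale neighbors) are
   keypoint candidates, refined to sub-pixel position/scale and filtered by
   a contrast threshold (on [0, 1] intensities) and an edge-response ratio;
3. a dominant gradient orientation per keypoint from a 36-bin, Gaussian
   weighted orientation histogram (secondary peaks >= 80% of the maximum
   spawn duplicate keypoints);
4. a 128-d descriptor: 4x4 spatial grid x 8 orientation bins of gradient
   magnitudes over a window scaled by the keypoint's sigma and rotated to
   its orientation, trilinearly binned, L2-normalized, clipped at 0.2 and
   re-normalized.

Everything here is deterministic; there is no randomness in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import to_luminance

__all__ = [
    "GaussianPyramid", "DoGPyramid", "Keypoint", "FeatureSet",
    "build_scale_space", "build_dog", "detect_keypoints",
    "assign_orientations", "compute_descriptors", "extract_features",
]

_ASSUMED_BLUR = 0.5  # nominal smoothing of the raw input image
_MIN_SIZE = 16


@dataclass
class GaussianPyramid:
    octaves: list  # octave o -> (s+3, H_o, W_o) stack
    sigma0: float
    k: float
    scales_per_octave: int
    upsampled: bool
    input_shape: tuple  # (H, W) of the original image

    @property
    def n_octaves(self) -> int:
        return len(self.octaves)

    def pixel_scale(self, octave: int) -> float:
        """Size of one pixel of ``octave`` in original-image pixels."""
        return 2.0 ** octave * (0.5 if self.upsampled else 1.0)


@dataclass
class DoGPyramid:
    octaves: list  # octave o -> (s+2, H_o, W_o) stack
    sigma0: float
    k: float
    scales_per_octave: int
    upsampled: bool
    input_shape: tuple

    def pixel_scale(self, octave: int) -> float:
        return 2.0 ** octave * (0.5 if self.upsampled else 1.0)


@dataclass
class Keypoint:
    """A localized scale-space extremum.

    ``x``/``y``/``sigma`` are in the original-image frame; ``x_oct``/
    ``y_oct``/``sigma_oct`` are the same quantities in the coordinate frame
    of ``octave`` (used by the orientation and descriptor stages).
    ``degenerate`` marks a zero-gradient neighborhood (orientation defaulted
    to 0) whose descriptor is excluded from encoding.
    """

    x: float
    y: float
    octave: int
    level: float
    sigma: float
    x_oct: float
    y_oct: float
    sigma_oct: float
    response: float
    orientation: float | None = None
    degenerate: bool = False


@dataclass
class FeatureSet:
    """Keypoints with their descriptors plus the source-image geometry
    (needed later for spatial-pyramid pooling)."""

    keypoints: list
    descriptors: np.ndarray  # (N, 128)
    image_size: tuple  # (W, H)

    def __len__(self) -> int:
        return len(self.keypoints)

    @property
    def positions(self) -> np.ndarray:
        return np.array([(kp.x, kp.y) for kp in self.keypoints]).reshape(-1, 2)


def _upsample2(img: np.ndarray) -> np.ndarray:
    return ndimage.zoom(img, 2.0, order=1, mode="nearest", grid_mode=True)


def build_scale_space(
    image: np.ndarray,
    sigma0: float = 1.6,
    scales_per_octave: int = 3,
    n_octaves: int | None = None,
    upsample: bool = True,
) -> GaussianPyramid:
    """Build the Gaussian pyramid.

    The number of octaves defaults to floor(log2(min(H, W))) - 2 of the
    input image. Each octave holds s + 3 levels; level j of octave o has
    absolute scale sigma0 * 2**o * k**j with k = 2**(1/s). The next
    octave's base is the level-s image downsampled by 2.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("build_scale_space expects a single-channel image")
    h, w = img.shape
    eff = (2 * h, 2 * w) if upsample else (h, w)
    if min(eff) < _MIN_SIZE:
        raise ValueError(
            f"image too small for scale space: need >= {_MIN_SIZE}x{_MIN_SIZE} "
            f"after optional 2x upsampling, got {eff[0]}x{eff[1]}"
        )
    s = int(scales_per_octave)
    if s < 1:
        raise ValueError("scales_per_octave must be >= 1")
    k = 2.0 ** (1.0 / s)
    if n_octaves is None:
        n_octaves = max(1, int(np.floor(np.log2(min(h, w)))) - 2)
    # never let an octave shrink below the DoG neighborhood
    max_oct = int(np.floor(np.log2(min(eff) / 8.0))) + 1
    n_octaves = max(1, min(n_octaves, max_oct))

    base = _upsample2(img) if upsample else img
    assumed = _ASSUMED_BLUR * (2.0 if upsample else 1.0)
    init = np.sqrt(max(sigma0 ** 2 - assumed ** 2, 0.01))
    base = ndimage.gaussian_filter(base, init, mode="nearest")

    octaves = []
    for _ in range(n_octaves):
        levels = [base]
        for j in range(1, s + 3):
            prev = sigma0 * k ** (j - 1)
            total = sigma0 * k ** j
            inc = np.sqrt(total ** 2 - prev ** 2)
            levels.append(ndimage.gaussian_filter(levels[-1], inc, mode="nearest"))
        octaves.append(np.stack(levels))
        base = levels[s][::2, ::2]
    return GaussianPyramid(
        octaves=octaves, sigma0=sigma0, k=k, scales_per_octave=s,
        upsampled=upsample, input_shape=(h, w),
    )


def build_dog(pyramid: GaussianPyramid) -> DoGPyramid:
    """Difference-of-Gaussians: adjacent pyramid levels subtracted exactly."""
    octs = [stack[1:] - stack[:-1] for stack in pyramid.octaves]
    return DoGPyramid(
        octaves=octs, sigma0=pyramid.sigma0, k=pyramid.k,
        scales_per_octave=pyramid.scales_per_octave,
        upsampled=pyramid.upsampled, input_shape=pyramid.input_shape,
    )


def _refine(D: np.ndarray, j: int, y: int, x: int, max_iter: int = 5):
    """Quadratic sub-pixel refinement of a DoG extremum.

    Returns (j, y, x, offset, value) or None when the candidate drifts out
    of the interior or never settles within the 0.5-pixel clamp.
    """
    L, H, W = D.shape
    off = np.zeros(3)
    for _ in range(max_iter):
        g = 0.5 * np.array([
            D[j + 1, y, x] - D[j - 1, y, x],
            D[j, y + 1, x] - D[j, y - 1, x],
            D[j, y, x + 1] - D[j, y, x - 1],
        ])
        c = D[j, y, x]
        hss = D[j + 1, y, x] + D[j - 1, y, x] - 2 * c
        hyy = D[j, y + 1, x] + D[j, y - 1, x] - 2 * c
        hxx = D[j, y, x + 1] + D[j, y, x - 1] - 2 * c
        hsy = 0.25 * (D[j + 1, y + 1, x] - D[j + 1, y - 1, x]
                      - D[j - 1, y + 1, x] + D[j - 1, y - 1, x])
        hsx = 0.25 * (D[j + 1, y, x + 1] - D[j + 1, y, x - 1]
                      - D[j - 1, y, x + 1] + D[j - 1, y, x - 1])
        hyx = 0.25 * (D[j, y + 1, x + 1] - D[j, y + 1, x - 1]
                      - D[j, y - 1, x + 1] + D[j, y - 1, x - 1])
        hess = np.array([[hss, hsy, hsx], [hsy, hyy, hyx], [hsx, hyx, hxx]])
        try:
            off = -np.linalg.solve(hess, g)
        except np.linalg.LinAlgError:
            return None
        if np.all(np.abs(off) <= 0.5):
            value = c + 0.5 * float(g @ off)
            return j, y, x, off, value
        j += int(np.clip(round(off[0]), -1, 1))
        y += int(np.clip(round(off[1]), -1, 1))
        x += int(np.clip(round(off[2]), -1, 1))
        if not (1 <= j < L - 1 and 1 <= y < H - 1 and 1 <= x < W - 1):
            return None
    return None


def detect_keypoints(
    dog: DoGPyramid,
    contrast_threshold: float = 0.03,
    edge_ratio: float = 10.0,
) -> list:
    """Find, refine and filter scale-space extrema.

    A candidate must be a strict extremum among its 26 neighbors; after
    sub-pixel interpolation it is kept only if |D| >= contrast_threshold
    (defined on [0, 1]-scaled intensities) and its 2x2 spatial Hessian
    satisfies trace**2/det < (r+1)**2/r with r = ``edge_ratio``. Border
    candidates (within 1 px of any space/scale boundary) are skipped.
    """
    keypoints = []
    r = edge_ratio
    edge_limit = (r + 1.0) ** 2 / r
    footprint = np.ones((3, 3, 3), bool)
    footprint[1, 1, 1] = False
    for o, D in enumerate(dog.octaves):
        L, H, W = D.shape
        if L < 3 or H < 3 or W < 3:
            continue
        nb_max = ndimage.maximum_filter(D, footprint=footprint, mode="constant", cval=-np.inf)
        nb_min = ndimage.minimum_filter(D, footprint=footprint, mode="constant", cval=np.inf)
        cand = (D > nb_max) | (D < nb_min)
        cand &= np.abs(D) >= 0.5 * contrast_threshold
        cand[[0, -1], :, :] = False
        cand[:, [0, -1], :] = False
        cand[:, :, [0, -1]] = False
        pix = dog.pixel_scale(o)
        h0, w0 = dog.input_shape
        for j, y, x in zip(*np.nonzero(cand)):
            res = _refine(D, int(j), int(y), int(x))
            if res is None:
                continue
            j2, y2, x2, off, value = res
            if abs(value) < contrast_threshold:
                continue
            c = D[j2, y2, x2]
            hyy = D[j2, y2 + 1, x2] + D[j2, y2 - 1, x2] - 2 * c
            hxx = D[j2, y2, x2 + 1] + D[j2, y2, x2 - 1] - 2 * c
            hyx = 0.25 * (D[j2, y2 + 1, x2 + 1] - D[j2, y2 + 1, x2 - 1]
                          - D[j2, y2 - 1, x2 + 1] + D[j2, y2 - 1, x2 - 1])
            tr, det = hxx + hyy, hxx * hyy - hyx * hyx
            if det <= 0 or tr * tr / det >= edge_limit:
                continue
            level = j2 + off[0]
            x_oct, y_oct = x2 + off[2], y2 + off[1]
            sigma_oct = dog.sigma0 * dog.k ** level
            xi, yi = x_oct * pix, y_oct * pix
            if not (0 <= xi < w0 and 0 <= yi < h0):
                continue
            keypoints.append(Keypoint(
                x=float(xi), y=float(yi), octave=o, level=float(level),
                sigma=float(sigma_oct * pix), x_oct=float(x_oct),
                y_oct=float(y_oct), sigma_oct=float(sigma_oct),
                response=float(value),
            ))
    return keypoints


class _GradientCache:
    """Central-difference gradients of pyramid levels, computed on demand."""

    def __init__(self, pyramid: GaussianPyramid):
        self.pyr = pyramid
        self._cache = {}

    def __call__(self, octave: int, level: int):
        key = (octave, level)
        if key not in self._cache:
            L = self.pyr.octaves[octave][level]
            dy = np.zeros_like(L)
            dx = np.zeros_like(L)
            dy[1:-1, :] = 0.5 * (L[2:, :] - L[:-2, :])
            dx[:, 1:-1] = 0.5 * (L[:, 2:] - L[:, :-2])
            self._cache[key] = (np.hypot(dx, dy), np.arctan2(dy, dx) % (2 * np.pi))
        return self._cache[key]


def _nearest_level(pyr: GaussianPyramid, kp: Keypoint) -> int:
    return int(np.clip(round(kp.level), 0, pyr.scales_per_octave + 2))


def assign_orientations(
    pyramid: GaussianPyramid,
    keypoints: list,
    num_bins: int = 36,
    peak_ratio: float = 0.8,
    sigma_factor: float = 1.5,
) -> list:
    """Fill keypoint orientations from the local gradient field.

    A 36-bin orientation histogram over a neighborhood Gaussian-weighted at
    1.5x the keypoint scale is smoothed and its parabolic-interpolated peaks
    assigned; every secondary peak >= 80% of the maximum emits an extra
    keypoint. A zero-gradient neighborhood keeps orientation 0 with the
    ``degenerate`` flag set.
    """
    grads = _GradientCache(pyramid)
    out = []
    two_pi = 2 * np.pi
    for kp in keypoints:
        lvl = _nearest_level(pyramid, kp)
        mag, ori = grads(kp.octave, lvl)
        h, w = mag.shape
        sw = sigma_factor * kp.sigma_oct
        radius = max(1, int(round(3.0 * sw)))
        cy, cx = int(round(kp.y_oct)), int(round(kp.x_oct))
        y0, y1 = max(0, cy - radius), min(h, cy + radius + 1)
        x0, x1 = max(0, cx - radius), min(w, cx + radius + 1)
        if y0 >= y1 or x0 >= x1:
            out.append(replace(kp, orientation=0.0, degenerate=True))
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        wgt = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * sw * sw))
        m = mag[y0:y1, x0:x1] * wgt
        bins = (ori[y0:y1, x0:x1] / two_pi * num_bins).astype(int) % num_bins
        hist = np.bincount(bins.ravel(), weights=m.ravel(), minlength=num_bins)
        for _ in range(6):  # circular smoothing damps spurious secondary peaks
            hist = (np.roll(hist, 1) + hist + np.roll(hist, -1)) / 3.0
        peak = hist.max()
        if peak <= 0:
            out.append(replace(kp, orientation=0.0, degenerate=True))
            continue
        left, right = np.roll(hist, 1), np.roll(hist, -1)
        is_peak = (hist > left) & (hist > right) & (hist >= peak_ratio * peak)
        idxs = np.nonzero(is_peak)[0]
        if len(idxs) == 0:
            idxs = [int(np.argmax(hist))]
        for i in idxs:
            denom = left[i] - 2 * hist[i] + right[i]
            off = 0.0 if denom == 0 else 0.5 * (left[i] - right[i]) / denom
            theta = ((i + 0.5 + off) * two_pi / num_bins) % two_pi
            out.append(replace(kp, orientation=float(theta)))
    return out


def compute_descriptors(
    pyramid: GaussianPyramid,
    keypoints: list,
    window_width: int = 4,
    num_bins: int = 8,
    scale_multiplier: float = 3.0,
    clip_value: float = 0.2,
) -> np.ndarray:
    """128-d gradient-histogram descriptors (4x4 grid x 8 orientation bins).

    Samples from a window scaled by the keypoint sigma and rotated to its
    orientation are trilinearly binned; the flattened histogram is
    L2-normalized, clipped at ``clip_value`` and re-normalized. Samples
    falling outside the image contribute zero. A zero-gradient window
    yields an all-zero descriptor and sets the keypoint's degenerate flag.
    """
    grads = _GradientCache(pyramid)
    two_pi = 2 * np.pi
    d = window_width
    descs = np.zeros((len(keypoints), d * d * num_bins))
    for n, kp in enumerate(keypoints):
        lvl = _nearest_level(pyramid, kp)
        mag, ori = grads(kp.octave, lvl)
        h, w = mag.shape
        theta = kp.orientation or 0.0
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        hist_width = scale_multiplier * kp.sigma_oct
        radius = int(round(hist_width * np.sqrt(2) * (d + 1) * 0.5))
        radius = min(radius, int(np.sqrt(h * h + w * w)))
        cy, cx = kp.y_oct, kp.x_oct
        y0, y1 = max(0, int(cy) - radius), min(h, int(cy) + radius + 1)
        x0, x1 = max(0, int(cx) - radius), min(w, int(cx) + radius + 1)
        if y0 >= y1 or x0 >= x1:
            keypoints[n] = replace(kp, degenerate=True)
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        dy, dx = (yy - cy).ravel(), (xx - cx).ravel()
        # rotate into the keypoint frame, in units of one sub-region
        xr = (cos_t * dx + sin_t * dy) / hist_width
        yr = (-sin_t * dx + cos_t * dy) / hist_width
        rbin = yr + 0.5 * d - 0.5
        cbin = xr + 0.5 * d - 0.5
        keep = (rbin > -1) & (rbin < d) & (cbin > -1) & (cbin < d)
        if not np.any(keep):
            keypoints[n] = replace(kp, degenerate=True)
            continue
        rbin, cbin = rbin[keep], cbin[keep]
        xr, yr = xr[keep], yr[keep]
        m = mag[y0:y1, x0:x1].ravel()[keep]
        m = m * np.exp(-(xr * xr + yr * yr) / (0.5 * d * d))
        obin = (((ori[y0:y1, x0:x1].ravel()[keep] - theta) % two_pi)
                / two_pi * num_bins)
        hist = np.zeros((d + 2, d + 2, num_bins))
        r0, c0, o0 = np.floor(rbin).astype(int), np.floor(cbin).astype(int), np.floor(obin).astype(int)
        fr, fc, fo = rbin - r0, cbin - c0, obin - o0
        o0 %= num_bins
        for dr in (0, 1):
            wr = m * (fr if dr else 1 - fr)
            for dc in (0, 1):
                wc = wr * (fc if dc else 1 - fc)
                for do in (0, 1):
                    wo = wc * (fo if do else 1 - fo)
                    np.add.at(hist, (r0 + 1 + dr, c0 + 1 + dc, (o0 + do) % num_bins), wo)
        vec = hist[1:-1, 1:-1, :].ravel()
        norm = np.linalg.norm(vec)
        if norm <= 0:
            keypoints[n] = replace(kp, degenerate=True)
            continue
        vec = np.minimum(vec / norm, clip_value)
        norm = np.linalg.norm(vec)
        descs[n] = vec / norm
    return descs


def extract_features(
    image: np.ndarray,
    sigma0: float = 1.6,
    scales_per_octave: int = 3,
    upsample: bool = True,
    contrast_threshold: float = 0.03,
    edge_ratio: float = 10.0,
    max_pixels: float | None = 8e6,
    dense_step: int | None = None,
) -> FeatureSet:
    """Run the full detector/descriptor stack on an image.

    RGB input is reduced to BT.601 luminance on [0, 1]. Degenerate
    (zero-gradient) keypoints are dropped so that every returned descriptor
    is a unit vector. Images above ``max_pixels`` are downscaled by powers
    of 2 first (keypoint coordinates are mapped back). ``dense_step``
    switches to a dense grid of unoriented keypoints at fixed scale instead
    of detected extrema.
    """
    img = np.asarray(image, dtype=np.float64)
    h0, w0 = img.shape[:2]
    if img.ndim == 3:
        lum = to_luminance(img)
    else:
        # heuristic for bare 2-D arrays: treat as 8-bit unless the values
        # already look like unit-scale intensities (mild interpolation
        # overshoot beyond 1.0 is tolerated)
        lum = img / 255.0 if img.size and img.max() > 2.0 else img
    factor = 1
    if max_pixels is not None:
        while lum.shape[0] * lum.shape[1] > max_pixels:
            lum = lum[::2, ::2]
            factor *= 2
    pyr = build_scale_space(lum, sigma0=sigma0, scales_per_octave=scales_per_octave,
                            upsample=upsample)
    if dense_step is not None:
        kps = []
        h, w = lum.shape
        for y in range(dense_step // 2, h, dense_step):
            for x in range(dense_step // 2, w, dense_step):
                sc = pyr.pixel_scale(0)
                kps.append(Keypoint(
                    x=float(x), y=float(y), octave=0, level=1.0,
                    sigma=sigma0 * pyr.k * sc, x_oct=x / sc, y_oct=y / sc,
                    sigma_oct=sigma0 * pyr.k, response=0.0, orientation=0.0,
                ))
    else:
        dog = build_dog(pyr)
        kps = detect_keypoints(dog, contrast_threshold=contrast_threshold,
                               edge_ratio=edge_ratio)
        kps = assign_orientations(pyr, kps)
    descs = compute_descriptors(pyr, kps)
    if factor > 1:
        kps = [replace(kp, x=kp.x * factor, y=kp.y * factor, sigma=kp.sigma * factor)
               for kp in kps]
    ok = [i for i, kp in enumerate(kps)
          if not kp.degenerate and 0 <= kp.x < w0 and 0 <= kp.y < h0]
    return FeatureSet(
        keypoints=[kps[i] for i in ok],
        descriptors=descs[ok] if ok else np.zeros((0, 128)),
        image_size=(w0, h0),
    )
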