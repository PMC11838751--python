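"""Isochrone and conduction-velocity mapping from calcium-imaging movies.

Mirrors the electrode pipeline on the optical side: mask out background and
electrode-occluded pixels, compute each pixel's activation time as the
half-maximum crossing of its locally averaged fluorescence trace, reduce the
LAT image with 5x5 max pooling, smooth it with a local 2-D quadratic
least-squares fit

    T(x, y) = a + b x + c y + d x^2 + e x y + f y^2,

and differentiate the smoothed field with central differences to obtain
planar CV direction and speed (speed = 1 / ||grad T||, via the physical
pixel pitch).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synth import FrameStack

__all__ = [
    "build_mask",
    "PixelLATMap",
    "pixel_lat",
    "pool_lat",
    "SmoothedLATMap",
    "smooth_lat",
    "CVField2D",
    "cv_2d",
    "calcium_pipeline",
]


@dataclass
class PixelLATMap:
    """Per-pixel activation times (seconds) with a validity mask."""

    lat: np.ndarray
    valid: np.ndarray
    pixel_size: float       # um / pixel of THIS map (grows under pooling)

    def __post_init__(self):
        self.lat = np.asarray(self.lat, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.lat.shape != self.valid.shape:
            raise ValueError("lat and valid shapes differ")


def build_mask(stack: FrameStack, occlusion: np.ndarray | None = None,
               threshold: float = 0.2) -> np.ndarray:
    """Foreground mask: pixels with temporal dynamic range above threshold.

    ``threshold`` is a fraction of the movie's maximum per-pixel dynamic
    range; pixels under a True ``occlusion`` entry (electrode footprints) are
    always excluded.  ``threshold = 0`` keeps the whole non-occluded field of
    view.  An all-flat movie (no dynamic range anywhere) raises.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    not_occ = np.ones(stack.image_shape, dtype=bool)
    if occlusion is not None:
        if occlusion.shape != stack.image_shape:
            raise ValueError("occlusion shape must match the movie")
        not_occ &= ~occlusion
    if threshold == 0:
        return not_occ
    dyn = stack.frames.max(axis=0) - stack.frames.min(axis=0)
    dmax = dyn[not_occ].max() if not_occ.any() else 0.0
    if dmax <= 0:
        raise ValueError("no fluorescence dynamic range: empty mask")
    mask = (dyn > threshold * dmax) & not_occ
    if not mask.any():
        raise ValueError("mask is empty at the requested threshold")
    return mask


def pixel_lat(stack: FrameStack, mask: np.ndarray, neighborhood: int = 3,
              baseline_percentile: float = 10.0) -> PixelLATMap:
    """Half-maximum upstroke time of every masked pixel.

    Each pixel's trace is the spatial mean over an odd ``neighborhood``
    square; baseline is a low percentile of the trace and the LAT is the
    first crossing of baseline + 0.5 (max - baseline), linearly interpolated
    between frames.  Pixels whose trace never rises above baseline are
    invalid.  The half-max criterion is invariant to global gain and offset.
    """
    if neighborhood < 1 or neighborhood % 2 == 0:
        raise ValueError("neighborhood must be odd and >= 1")
    frames = stack.frames
    if neighborhood > 1:
        frames = ndimage.uniform_filter(
            frames, size=(1, neighborhood, neighborhood), mode="nearest")
    baseline = np.percentile(frames, baseline_percentile, axis=0)
    peak = frames.max(axis=0)
    thr = baseline + 0.5 * (peak - baseline)
    rise = peak - baseline

    above = frames >= thr[None, :, :]
    first = np.argmax(above, axis=0)             # 0 if never above
    crossed = above.any(axis=0) & (rise > 0)
    valid = np.asarray(mask, dtype=bool) & crossed

    lat = np.full(stack.image_shape, np.nan)
    k = first
    km1 = np.clip(k - 1, 0, None)
    idx = np.indices(stack.image_shape)
    v1 = frames[k, idx[0], idx[1]]
    v0 = frames[km1, idx[0], idx[1]]
    with np.errstate(divide="ignore", invalid="ignore"):
        fracs = np.where(v1 > v0, (thr - v0) / (v1 - v0), 0.0)
    t = np.where(k > 0, km1 + np.clip(fracs, 0.0, 1.0), 0.0) / stack.frame_rate
    lat[valid] = t[valid]
    return PixelLATMap(lat, valid, stack.pixel_size)


def pool_lat(m: PixelLATMap, window: int = 5, mode: str = "max"
             ) -> PixelLATMap:
    """Non-overlapping window pooling of a LAT map.

    ``max`` (the default) takes each window's latest valid activation;
    ``mean`` averages valid pixels instead.  Windows with no valid pixel are
    invalid.  Output dimensions are ceil(input / window) and the pixel pitch
    grows by the window factor.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    h, w = m.lat.shape
    ph = -(-h // window) * window
    pw = -(-w // window) * window
    padded = np.full((ph, pw), np.nan)
    padded[:h, :w] = np.where(m.valid, m.lat, np.nan)
    blocks = padded.reshape(ph // window, window, pw // window, window)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(ph // window, pw // window,
                                                  -1)
    valid = np.any(np.isfinite(blocks), axis=-1)
    pooled = np.full(valid.shape, np.nan)
    if valid.any():
        reducer = np.nanmax if mode == "max" else np.nanmean
        pooled[valid] = reducer(blocks[valid], axis=-1)
    return PixelLATMap(pooled, valid, m.pixel_size * window)


@dataclass
class SmoothedLATMap:
    """Locally quadratic-smoothed LAT map plus per-pixel fit coefficients."""

    lat: np.ndarray
    valid: np.ndarray
    pixel_size: float                  # um / pixel
    coeffs: np.ndarray                 # (h, w, 6): a, b, c, d, e, f
    residual_rms: np.ndarray           # (h, w)


def fit_quadratic(x, y, t):
    """Least-squares T(x,y) = a + bx + cy + dx^2 + exy + fy^2.

    Returns (coeffs[6], residual rms).  Exact (zero residual) when the data
    lie in the model class.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    if t.size < 6:
        raise ValueError("need >= 6 points for a quadratic surface")
    A = np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])
    coef, *_ = np.linalg.lstsq(A, t, rcond=None)
    res = A @ coef - t
    return coef, float(np.sqrt(np.mean(res ** 2)))


def smooth_lat(m: PixelLATMap, window_um: float = 600.0,
               min_points: int = 6) -> SmoothedLATMap:
    """Local 2-D quadratic smoothing of a (pooled) LAT map.

    For every valid pixel a quadratic surface is least-squares fitted to the
    valid pixels inside a square neighborhood of physical side ``window_um``
    (in local pixel coordinates centered on the pixel), and the smoothed
    value is the fitted constant term a, i.e. the surface value at the
    center.  Pixels with fewer than ``min_points`` valid neighbors become
    invalid.
    """
    half = max(int(round(window_um / m.pixel_size / 2.0)), 1)
    h, w = m.lat.shape
    sm = np.full((h, w), np.nan)
    coeffs = np.full((h, w, 6), np.nan)
    rms = np.full((h, w), np.nan)
    valid_out = np.zeros((h, w), dtype=bool)
    for i in range(h):
        i0, i1 = max(i - half, 0), min(i + half + 1, h)
        for j in range(w):
            if not m.valid[i, j]:
                continue
            j0, j1 = max(j - half, 0), min(j + half + 1, w)
            sub = m.lat[i0:i1, j0:j1]
            vs = m.valid[i0:i1, j0:j1]
            if vs.sum() < min_points:
                continue
            yy, xx = np.nonzero(vs)
            try:
                coef, r = fit_quadratic(xx + j0 - j, yy + i0 - i, sub[yy, xx])
            except ValueError:
                continue
            sm[i, j] = coef[0]
            coeffs[i, j] = coef
            rms[i, j] = r
            valid_out[i, j] = True
    return SmoothedLATMap(sm, valid_out, m.pixel_size, coeffs, rms)


@dataclass
class CVField2D:
    """Planar conduction-velocity field on a pixel grid."""

    direction_x: np.ndarray
    direction_y: np.ndarray
    speed: np.ndarray        # cm/s
    valid: np.ndarray
    pixel_size: float        # um / pixel

    def valid_speeds(self) -> np.ndarray:
        return self.speed[self.valid]


def cv_2d(lat: np.ndarray, valid: np.ndarray, pixel_size_um: float,
          min_grad: float = 1e-3) -> CVField2D:
    """Central-difference CV field of a 2-D LAT map.

    Gradients are (T(x+1) - T(x-1)) / (2 dpixel) with dpixel the physical
    pixel pitch in cm; direction is the normalized gradient and speed its
    inverse magnitude in cm/s.  A pixel is valid only if itself and its four
    neighbors are valid and the gradient magnitude exceeds ``min_grad``
    (s/cm).
    """
    lat = np.asarray(lat, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if lat.ndim != 2 or min(lat.shape) < 3:
        raise ValueError("LAT map must be at least 3 x 3")
    dpix_cm = pixel_size_um * 1e-4
    h, w = lat.shape
    gx = np.full((h, w), np.nan)
    gy = np.full((h, w), np.nan)
    gx[:, 1:-1] = (lat[:, 2:] - lat[:, :-2]) / (2.0 * dpix_cm)
    gy[1:-1, :] = (lat[2:, :] - lat[:-2, :]) / (2.0 * dpix_cm)
    ok = valid.copy()
    ok[:, [0, -1]] = False
    ok[[0, -1], :] = False
    ok[:, 1:-1] &= valid[:, 2:] & valid[:, :-2]
    ok[1:-1, :] &= valid[2:, :] & valid[:-2, :]
    mag = np.hypot(gx, gy)
    ok &= np.isfinite(mag) & (mag > min_grad)
    with np.errstate(divide="ignore", invalid="ignore"):
        ux = np.where(ok, gx / mag, 0.0)
        uy = np.where(ok, gy / mag, 0.0)
        speed = np.where(ok, 1.0 / mag, np.nan)
    return CVField2D(ux, uy, speed, ok, pixel_size_um)


def calcium_pipeline(stack: FrameStack, occlusion: np.ndarray | None = None,
                     mask_threshold: float = 0.2, neighborhood: int = 3,
                     pool_window: int = 5, pool_mode: str = "max",
                     window_um: float = 600.0
                     ) -> tuple[PixelLATMap, PixelLATMap, SmoothedLATMap,
                                CVField2D]:
    """Full movie -> (pixel LAT, pooled LAT, smoothed LAT, CV field) chain."""
    mask = build_mask(stack, occlusion, mask_threshold)
    pix = pixel_lat(stack, mask, neighborhood)
    pooled = pool_lat(pix, pool_window, pool_mode)
    smoothed = smooth_lat(pooled, window_um)
    field = cv_2d(smoothed.lat, smoothed.valid, smoothed.pixel_size)
    return pix, pooled, smoothed, field
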