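"""Cross-modality comparison of electrode-derived and calcium-derived maps.

A fluorescence microscope only sees one hemisphere, so the 3-D electrode
isochrone map is reduced to the microscope's view before comparison: the 12
electrodes of the chosen hemisphere (8 equatorial + 4 polar-ring) are
re-interpolated and the visible hemisphere is orthographically projected
along the polar axis onto a pixel grid.  The projection is computed
analytically from the interpolant rather than decoded from rendered
screenshots, which removes the renderer/colormap round trip while producing
the same map content.

Maps are compared pixel-wise over co-valid pixels with Pearson correlation
and mean absolute error expressed as a percentage of the reference map's LAT
range; CV fields are compared through their valid-speed distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from skimage.transform import resize

from .spheremap import (ElectrodeLayout, RBFConfig, _SCHEMES,
                        orthographic_grid)

__all__ = [
    "ProjectionMap",
    "project_hemisphere",
    "MapComparison",
    "compare_maps",
    "resize_map",
    "compare_cv",
]


@dataclass
class ProjectionMap:
    """Orthographic 2-D LAT image of one hemisphere (seconds)."""

    lat: np.ndarray
    valid: np.ndarray
    pixel_size: float        # um / pixel
    view: str                # 'upper' | 'lower'


def project_hemisphere(layout: ElectrodeLayout, node_lats, view: str,
                       cfg: RBFConfig | None = None,
                       image_shape: tuple = (64, 64),
                       pixel_size_um: float | None = None,
                       scheme: str = "exact") -> ProjectionMap:
    """Hemisphere-restricted re-interpolation projected to a pixel grid.

    Only the 12 electrodes of the requested hemisphere are used, mirroring
    the reduction to what the microscope can corroborate.  ``pixel_size_um``
    defaults to the value that makes the projected disk fill ~90% of the
    image.  Raises if the hemisphere subset has fewer than 12 electrodes
    with finite LATs.
    """
    node_lats = np.asarray(node_lats, dtype=float)
    idx = layout.hemisphere_indices(view)
    idx = idx[np.isfinite(node_lats[idx])]
    if idx.size < 12:
        raise ValueError("fewer than 12 usable electrodes in the "
                         f"{view} hemisphere")
    sub = layout.subset(idx)
    sub_lats = node_lats[idx]
    if cfg is None:
        cfg = RBFConfig.for_layout(sub)
    if pixel_size_um is None:
        pixel_size_um = 2.0 * layout.radius_cm * 1e4 / (0.9 * min(image_shape))
    if scheme not in _SCHEMES:
        raise ValueError("scheme must be 'exact' or 'smoother'")
    phi, lam, inside = orthographic_grid(image_shape, pixel_size_um * 1e-4,
                                         layout.radius_cm, view)
    img = np.full(image_shape, np.nan)
    img[inside] = _SCHEMES[scheme](phi[inside], lam[inside], sub, sub_lats,
                                   cfg)
    return ProjectionMap(img, inside, pixel_size_um, view)


@dataclass
class MapComparison:
    pearson_r: float
    mae_percent: float       # % of the reference map's LAT range
    n_pixels: int
    mae_seconds: float


def resize_map(lat: np.ndarray, valid: np.ndarray, shape: tuple
               ) -> tuple[np.ndarray, np.ndarray]:
    """Rescale a LAT image (and its mask) to new pixel dimensions."""
    lat_f = np.where(valid, lat, 0.0)
    w = resize(valid.astype(float), shape, order=1, anti_aliasing=False)
    v = resize(lat_f, shape, order=1, anti_aliasing=False)
    out_valid = w > 0.999
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(out_valid, v / np.where(w > 0, w, 1.0), np.nan)
    return out, out_valid


def compare_maps(a_lat, a_valid, b_lat, b_valid, min_pixels: int = 10,
                 zero_align: bool = False) -> MapComparison:
    """Pearson r and MAE between two 2-D LAT maps of equal pixel dimensions.

    Computed over pixels valid in both maps; MAE is normalized by the
    reference (second) map's LAT range over those pixels.  With
    ``zero_align`` each map's co-valid minimum is subtracted first — maps
    from different modalities carry unrelated absolute time origins, and
    isochrone maps are conventionally zeroed at first activation (Pearson r
    is unaffected).  Raises when either map has zero variance (correlation
    undefined) or fewer than ``min_pixels`` pixels coincide.
    """
    a_lat = np.asarray(a_lat, dtype=float)
    b_lat = np.asarray(b_lat, dtype=float)
    if a_lat.shape != b_lat.shape:
        raise ValueError("maps must share pixel dimensions; resize first")
    both = (np.asarray(a_valid, bool) & np.asarray(b_valid, bool)
            & np.isfinite(a_lat) & np.isfinite(b_lat))
    n = int(both.sum())
    if n < min_pixels:
        raise ValueError(f"only {n} co-valid pixels (need >= {min_pixels})")
    a = a_lat[both]
    b = b_lat[both]
    if zero_align:
        a = a - a.min()
        b = b - b.min()
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("zero variance in a map: correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    mae = float(np.mean(np.abs(a - b)))
    return MapComparison(r, 100.0 * mae / float(np.ptp(b)), n, mae)


def compare_cv(fields: dict) -> dict:
    """Valid-speed distribution summary per named CV field.

    ``fields`` maps name -> object with a ``valid_speeds()`` method (3-D
    :class:`~shellmea.spheremap.CVField` or planar
    :class:`~shellmea.calcium.CVField2D`).  Raises on a field with no valid
    nodes.
    """
    out = {}
    for name, f in fields.items():
        v = np.asarray(f.valid_speeds(), dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError(f"CV field '{name}' has no valid nodes")
        out[name] = {
            "n": int(v.size),
            "mean_cm_s": float(v.mean()),
            "median_cm_s": float(np.median(v)),
            "p25_cm_s": float(np.percentile(v, 25)),
            "p75_cm_s": float(np.percentile(v, 75)),
        }
    return out
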