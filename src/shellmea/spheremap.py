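"""Spherical isochrone interpolation and conduction-velocity vector mapping.

The 16 electrodes of a folded shell MEA sit on an (assumed ideal) sphere in
three rings: four near the bottom, eight at the equator, four near the top.
Given one local activation time (LAT) per electrode, this module spreads
those 16 samples over the whole sphere with inverse-quadratic
radial-basis-function (RBF) interpolation of great-circle (haversine)
distance, and differentiates the resulting scalar field with central finite
differences in local east/north arc-length coordinates to obtain
conduction-velocity (CV) unit vectors and speeds (speed = 1/||grad LAT||).

Two RBF evaluation schemes are provided.  The normalized-weight smoother

    w_i = 1 / (1 + (d_i / eps)^2),   LAT(p) = sum_i w_i LAT_i / sum_i w_i,

is a convex combination of the electrode LATs (bounded by their min/max) but
does not pass through them and compresses gradients — speeds read off such a
map are biased high.  The exact scheme solves the kernel system so the
surface honors every electrode LAT and its gradients are faithful; it is
the default for map building and the only sound basis for CV estimation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "RBFConfig",
    "SphereGrid",
    "IsochroneMap3D",
    "CVField",
    "haversine",
    "rbf_weight",
    "interpolate_lat",
    "build_isochrone",
    "cv_field",
    "export_vtk",
    "read_vtk_polydata",
    "orthographic_grid",
    "circumradius_3pt",
]


# ---------------------------------------------------------------------------
# geometry primitives
# ---------------------------------------------------------------------------

def haversine(phi1, lam1, phi2, lam2, r=1.0):
    """Great-circle distance between points (latitude phi, longitude lam).

    Angles in radians, distance in the units of ``r``.  Vectorized over any
    broadcastable combination of inputs.  The arcsin argument is clipped to
    [0, 1] to guard against rounding for antipodal points.
    """
    phi1, lam1, phi2, lam2 = np.broadcast_arrays(phi1, lam1, phi2, lam2)
    if not (np.all(np.isfinite(phi1)) and np.all(np.isfinite(lam1))
            and np.all(np.isfinite(phi2)) and np.all(np.isfinite(lam2))):
        raise ValueError("haversine: coordinates must be finite")
    if r <= 0:
        raise ValueError("haversine: sphere radius must be > 0")
    a = (np.sin((phi2 - phi1) / 2.0) ** 2
         + np.cos(phi1) * np.cos(phi2) * np.sin((lam2 - lam1) / 2.0) ** 2)
    return 2.0 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def sphere_to_cart(phi, lam, r=1.0):
    """(lat, lon) -> (x, y, z) with z along the polar axis."""
    phi = np.asarray(phi, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return (r * np.cos(phi) * np.cos(lam),
            r * np.cos(phi) * np.sin(lam),
            r * np.sin(phi))


# ---------------------------------------------------------------------------
# electrode layout
# ---------------------------------------------------------------------------

_LOWER_LONS_DEG = (0.0, 90.0, 180.0, 270.0)
_UPPER_LONS_DEG = (0.0, 90.0, 180.0, 270.0)
_EQUATOR_LONS_DEG = tuple(float(x) for x in range(0, 360, 45))


@dataclass(frozen=True)
class ElectrodeLayout:
    """Spherical positions of the 16 shell-MEA electrodes.

    ``phi``/``lam`` are latitude/longitude in radians; ``radius_cm`` is the
    sphere (organoid) radius in cm.  The default layout places four
    electrodes at -45 deg latitude, eight at the equator and four at +45 deg,
    with the four-electrode rings at longitudes 0/90/180/270 deg and the
    equatorial ring stepping 45 deg.
    """

    channel_ids: tuple
    phi: np.ndarray
    lam: np.ndarray
    radius_cm: float

    def __post_init__(self):
        object.__setattr__(self, "phi", np.asarray(self.phi, dtype=float))
        object.__setattr__(self, "lam", np.asarray(self.lam, dtype=float))
        if len(self.channel_ids) != len(set(self.channel_ids)):
            raise ValueError("channel_ids must be unique")
        if not (len(self.channel_ids) == self.phi.size == self.lam.size):
            raise ValueError("channel_ids, phi, lam must have equal length")
        if self.radius_cm <= 0:
            raise ValueError("sphere radius must be > 0")

    @property
    def n_electrodes(self) -> int:
        return len(self.channel_ids)

    @classmethod
    def default(cls, radius_cm: float = 0.025,
                lower_lat_deg: float = -45.0,
                upper_lat_deg: float = 45.0) -> "ElectrodeLayout":
        lats, lons = [], []
        for lon in _LOWER_LONS_DEG:
            lats.append(lower_lat_deg); lons.append(lon)
        for lon in _EQUATOR_LONS_DEG:
            lats.append(0.0); lons.append(lon)
        for lon in _UPPER_LONS_DEG:
            lats.append(upper_lat_deg); lons.append(lon)
        ids = tuple(f"E{i:02d}" for i in range(1, len(lats) + 1))
        return cls(ids, np.radians(lats), np.radians(lons), radius_cm)

    def subset(self, indices) -> "ElectrodeLayout":
        indices = np.asarray(indices, dtype=int)
        return ElectrodeLayout(tuple(self.channel_ids[i] for i in indices),
                               self.phi[indices], self.lam[indices],
                               self.radius_cm)

    def hemisphere_indices(self, view: str) -> np.ndarray:
        """Equatorial electrodes plus the polar ring facing ``view``."""
        if view == "upper":
            keep = self.phi > -1e-12
        elif view == "lower":
            keep = self.phi < 1e-12
        else:
            raise ValueError("view must be 'upper' or 'lower'")
        return np.nonzero(keep)[0]

    def nearest_neighbor_spacing(self) -> float:
        """Mean over electrodes of the haversine distance to the nearest other."""
        d = haversine(self.phi[:, None], self.lam[:, None],
                      self.phi[None, :], self.lam[None, :], self.radius_cm)
        np.fill_diagonal(d, np.inf)
        return float(d.min(axis=1).mean())

    def rotated(self, dlam: float) -> "ElectrodeLayout":
        """Layout rotated by ``dlam`` radians about the polar axis."""
        return replace(self, lam=self.lam + dlam)

    # -- JSON round trip (degrees + radius in um on disk) -------------------
    def to_json_dict(self) -> dict:
        return {
            "units": {"angles": "degrees", "radius": "um"},
            "radius": self.radius_cm * 1e4,
            "electrodes": [
                {"id": cid, "lat": float(np.degrees(p)),
                 "lon": float(np.degrees(l))}
                for cid, p, l in zip(self.channel_ids, self.phi, self.lam)
            ],
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ElectrodeLayout":
        units = d.get("units", {})
        ang = units.get("angles", "degrees")
        rad_unit = units.get("radius", "um")
        conv = np.radians if ang == "degrees" else np.asarray
        r = float(d["radius"])
        r_cm = r * 1e-4 if rad_unit == "um" else r
        ids = tuple(e["id"] for e in d["electrodes"])
        phi = conv([float(e["lat"]) for e in d["electrodes"]])
        lam = conv([float(e["lon"]) for e in d["electrodes"]])
        return cls(ids, phi, lam, r_cm)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "ElectrodeLayout":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


# ---------------------------------------------------------------------------
# RBF interpolation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RBFConfig:
    """Shape parameter of the inverse-quadratic RBF, in distance units (cm)."""

    epsilon: float

    def __post_init__(self):
        if not (self.epsilon > 0):
            raise ValueError("RBF epsilon must be > 0")

    @classmethod
    def for_layout(cls, layout: ElectrodeLayout) -> "RBFConfig":
        """Default shape parameter: mean nearest-neighbor electrode spacing."""
        return cls(layout.nearest_neighbor_spacing())


def rbf_weight(d, epsilon):
    """Inverse-quadratic kernel 1 / (1 + (d/eps)^2); 1 at d=0, decreasing."""
    if epsilon <= 0:
        raise ValueError("RBF epsilon must be > 0")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    return 1.0 / (1.0 + (d / epsilon) ** 2)


def _query_weights(phi, lam, layout: ElectrodeLayout, epsilon: float):
    phi = np.asarray(phi, dtype=float)
    lam = np.asarray(lam, dtype=float)
    shape = np.broadcast_shapes(phi.shape, lam.shape)
    qphi = np.broadcast_to(phi, shape).reshape(-1, 1)
    qlam = np.broadcast_to(lam, shape).reshape(-1, 1)
    d = haversine(qphi, qlam, layout.phi[None, :], layout.lam[None, :],
                  layout.radius_cm)
    return rbf_weight(d, epsilon), shape


def _check_node_lats(layout, node_lats):
    node_lats = np.asarray(node_lats, dtype=float)
    if node_lats.shape != (layout.n_electrodes,):
        raise ValueError("node_lats must have one value per electrode")
    if not np.all(np.isfinite(node_lats)):
        raise ValueError("node LATs must be finite")
    return node_lats


def interpolate_lat(phi, lam, layout: ElectrodeLayout, node_lats,
                    cfg: RBFConfig):
    """Normalized-weight RBF smoothing of electrode LATs at query points.

    The weighted-mean rule sum(w_i LAT_i) / sum(w_i) with inverse-quadratic
    weights of haversine distance.  Returns seconds with the shape of
    ``phi``/``lam``.  Output is a convex combination of ``node_lats`` and
    therefore bounded by their range; the price is that the surface does not
    pass through the electrode values and its gradients are systematically
    compressed (see :func:`rbf_exact` and the methods note).
    """
    node_lats = _check_node_lats(layout, node_lats)
    w, shape = _query_weights(phi, lam, layout, cfg.epsilon)
    wsum = w.sum(axis=1)
    # inverse-quadratic weights are >= eps^2/(eps^2+d^2) > 0, so wsum > 0
    assert np.all(wsum > 0), "RBF weights underflowed to zero"
    vals = (w @ node_lats) / wsum
    return vals.reshape(shape)


def rbf_exact(phi, lam, layout: ElectrodeLayout, node_lats, cfg: RBFConfig):
    """Exact inverse-quadratic RBF interpolation of electrode LATs.

    Solves the 16 x 16 kernel system K c = LAT - mean(LAT) (K_ij the
    inverse-quadratic kernel of the inter-electrode haversine distances) so
    the surface passes through every electrode value; queries evaluate
    mean(LAT) + sum(c_i K(d_i)).  Fitting residuals about the mean makes a
    constant field reproduce exactly.  Unlike the normalized-weight smoother
    this scheme preserves the field's gradients, which is what
    conduction-velocity estimation needs.
    """
    node_lats = _check_node_lats(layout, node_lats)
    D = haversine(layout.phi[:, None], layout.lam[:, None],
                  layout.phi[None, :], layout.lam[None, :], layout.radius_cm)
    K = rbf_weight(D, cfg.epsilon)
    offset = node_lats.mean()
    coef = np.linalg.solve(K, node_lats - offset)
    w, shape = _query_weights(phi, lam, layout, cfg.epsilon)
    return (offset + w @ coef).reshape(shape)


_SCHEMES = {"exact": rbf_exact, "smoother": interpolate_lat}


# ---------------------------------------------------------------------------
# grid, isochrone map, CV field
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereGrid:
    """Regular latitude-longitude grid, poles excluded by half-step offset."""

    n_lat: int = 64
    n_lon: int = 128

    def __post_init__(self):
        if self.n_lat < 3 or self.n_lon < 3:
            raise ValueError("grid must be at least 3 x 3")

    @property
    def dphi(self) -> float:
        return math.pi / self.n_lat

    @property
    def dlam(self) -> float:
        return 2.0 * math.pi / self.n_lon

    @property
    def latitudes(self) -> np.ndarray:
        return -math.pi / 2 + (np.arange(self.n_lat) + 0.5) * self.dphi

    @property
    def longitudes(self) -> np.ndarray:
        return (np.arange(self.n_lon) + 0.5) * self.dlam

    def mesh(self):
        """(phi, lam) 2-D arrays of shape (n_lat, n_lon)."""
        return np.meshgrid(self.latitudes, self.longitudes, indexing="ij")


@dataclass
class IsochroneMap3D:
    """Activation-time scalar field on a :class:`SphereGrid` (seconds)."""

    grid: SphereGrid
    values: np.ndarray
    radius_cm: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_lat, self.grid.n_lon):
            raise ValueError("values shape must match grid")


@dataclass
class CVField:
    """Unit direction (east, north components) and speed of propagation."""

    grid: SphereGrid
    direction_east: np.ndarray
    direction_north: np.ndarray
    speed: np.ndarray          # cm/s
    valid: np.ndarray          # bool mask
    radius_cm: float = field(default=0.025)

    def valid_speeds(self) -> np.ndarray:
        return self.speed[self.valid]


def build_isochrone(layout: ElectrodeLayout, node_lats, grid: SphereGrid,
                    cfg: RBFConfig, scheme: str = "exact") -> IsochroneMap3D:
    """Spherical isochrone map: RBF evaluation at every grid node.

    ``scheme``: ``"exact"`` (default; interpolant passes through the
    electrode LATs, gradients faithful — required for CV mapping) or
    ``"smoother"`` (normalized weighted mean; bounded by the node range but
    gradient-compressing).
    """
    if scheme not in _SCHEMES:
        raise ValueError("scheme must be 'exact' or 'smoother'")
    phi, lam = grid.mesh()
    vals = _SCHEMES[scheme](phi, lam, layout, node_lats, cfg)
    return IsochroneMap3D(grid, vals, layout.radius_cm)


# default mask tolerance: gradients below (1 ms over a half-circumference)
def _default_min_grad(radius_cm: float) -> float:
    return 1e-3 / (math.pi * radius_cm)


def cv_field(isomap: IsochroneMap3D, min_grad: float | None = None,
             metric_correction: bool = True) -> CVField:
    """Finite-difference conduction-velocity field of an isochrone map.

    East/west differences wrap in longitude; the top and bottom latitude rows
    use one-sided north/south differences.  Local spacings are arc lengths:
    east spacing r*cos(phi)*dlam (the cos(phi) metric factor can be disabled
    with ``metric_correction=False``), north spacing r*dphi.  Speed is the
    inverse gradient magnitude in cm/s; nodes with gradient magnitude below
    ``min_grad`` (s/cm) are masked invalid.
    """
    grid, T, r = isomap.grid, isomap.values, isomap.radius_cm
    if min_grad is None:
        min_grad = _default_min_grad(r)
    phi = grid.latitudes[:, None]
    cosphi = np.cos(phi) if metric_correction else np.ones_like(phi)
    dd_east = r * cosphi * grid.dlam
    dd_north = r * grid.dphi

    grad_e = (np.roll(T, -1, axis=1) - np.roll(T, 1, axis=1)) / (2.0 * dd_east)
    grad_n = np.empty_like(T)
    grad_n[1:-1, :] = (T[2:, :] - T[:-2, :]) / (2.0 * dd_north)
    grad_n[0, :] = (T[1, :] - T[0, :]) / dd_north
    grad_n[-1, :] = (T[-1, :] - T[-2, :]) / dd_north

    mag = np.hypot(grad_e, grad_n)
    valid = mag > min_grad
    with np.errstate(divide="ignore", invalid="ignore"):
        ue = np.where(valid, grad_e / mag, 0.0)
        un = np.where(valid, grad_n / mag, 0.0)
        speed = np.where(valid, 1.0 / mag, np.nan)
    if not valid.any():
        import warnings
        warnings.warn("all-constant isochrone map: CV field fully masked",
                      stacklevel=2)
    return CVField(grid, ue, un, speed, valid, radius_cm=r)


# ---------------------------------------------------------------------------
# orthographic hemisphere projection (shared with calcium simulation)
# ---------------------------------------------------------------------------

def orthographic_grid(image_shape, pixel_size_cm: float, radius_cm: float,
                      view: str):
    """Map image pixels to sphere surface points for a polar-axis view.

    Returns ``(phi, lam, inside)`` arrays of the image shape: latitude and
    longitude of the visible-hemisphere point under each pixel, and a boolean
    mask of pixels inside the projected disk.  The image x axis is +X for the
    upper view and -X for the lower view (what a viewer underneath, looking
    up, sees), so left/right follow the physical viewing geometry.
    """
    if view not in ("upper", "lower"):
        raise ValueError("view must be 'upper' or 'lower'")
    h, w = image_shape
    if min(h, w) * pixel_size_cm < 2.0 * radius_cm:
        raise ValueError("image too small to contain the projected sphere")
    ys = (np.arange(h) - (h - 1) / 2.0) * pixel_size_cm
    xs = (np.arange(w) - (w - 1) / 2.0) * pixel_size_cm
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    if view == "lower":
        X = -X
    rho2 = X ** 2 + Y ** 2
    inside = rho2 <= radius_cm ** 2
    Z = np.sqrt(np.clip(radius_cm ** 2 - rho2, 0.0, None))
    if view == "lower":
        Z = -Z
    with np.errstate(invalid="ignore"):
        phi = np.arcsin(np.clip(Z / radius_cm, -1.0, 1.0))
    lam = np.arctan2(Y, X)
    phi = np.where(inside, phi, 0.0)
    lam = np.where(inside, lam, 0.0)
    return phi, lam, inside


# ---------------------------------------------------------------------------
# legacy-VTK ASCII export
# ---------------------------------------------------------------------------

def _grid_points(grid: SphereGrid, r: float) -> np.ndarray:
    phi, lam = grid.mesh()
    x, y, z = sphere_to_cart(phi, lam, r)
    return np.column_stack([x.ravel(), y.ravel(), z.ravel()])


def _tangent_vectors(field: CVField) -> np.ndarray:
    """CV unit vectors expressed in 3-D cartesian tangent coordinates."""
    phi, lam = field.grid.mesh()
    east = np.stack([-np.sin(lam), np.cos(lam), np.zeros_like(lam)], axis=-1)
    north = np.stack([-np.sin(phi) * np.cos(lam),
                      -np.sin(phi) * np.sin(lam),
                      np.cos(phi)], axis=-1)
    vec = (field.direction_east[..., None] * east
           + field.direction_north[..., None] * north)
    vec[~field.valid] = 0.0
    return vec.reshape(-1, 3)


def export_vtk(path, isomap: IsochroneMap3D | None = None,
               cvf: CVField | None = None) -> None:
    """Write a legacy-VTK ASCII polydata sphere mesh.

    Point scalars ``LAT`` (seconds) come from ``isomap``; point vectors ``CV``
    (unit direction, tangent to the sphere) and scalars ``speed`` from
    ``cvf``.  At least one of the two must be given; grids must agree when
    both are.
    """
    src = isomap if isomap is not None else cvf
    if src is None:
        raise ValueError("need an isochrone map and/or a CV field")
    if isomap is not None and cvf is not None and isomap.grid != cvf.grid:
        raise ValueError("isochrone and CV grids differ")
    grid, r = src.grid, src.radius_cm
    pts = _grid_points(grid, r)
    nlat, nlon = grid.n_lat, grid.n_lon

    def node(i, j):
        return i * nlon + (j % nlon)

    quads = [(node(i, j), node(i, j + 1), node(i + 1, j + 1), node(i + 1, j))
             for i in range(nlat - 1) for j in range(nlon)]

    lines = ["# vtk DataFile Version 3.0",
             "shellmea sphere map", "ASCII", "DATASET POLYDATA",
             f"POINTS {len(pts)} float"]
    lines += [f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for p in pts]
    lines.append(f"POLYGONS {len(quads)} {5 * len(quads)}")
    lines += [f"4 {a} {b} {c} {d}" for a, b, c, d in quads]
    lines.append(f"POINT_DATA {len(pts)}")
    if isomap is not None:
        lines.append("SCALARS LAT float 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.9g}" for v in isomap.values.ravel()]
    if cvf is not None:
        lines.append("SCALARS speed float 1")
        lines.append("LOOKUP_TABLE default")
        speed = np.where(cvf.valid, cvf.speed, 0.0).ravel()
        lines += [f"{v:.9g}" for v in speed]
        lines.append("VECTORS CV float")
        lines += [f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}"
                  for v in _tangent_vectors(cvf)]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk_polydata(path) -> dict:
    """Minimal legacy-VTK ASCII reader (round-trip checks of export_vtk)."""
    with open(path) as fh:
        tokens = fh.read().split("\n")
    out: dict = {"scalars": {}, "vectors": {}}
    i = 0
    npts = 0
    while i < len(tokens):
        line = tokens[i].strip()
        parts = line.split()
        if not parts:
            i += 1
            continue
        key = parts[0]
        if key == "POINTS":
            npts = int(parts[1])
            vals = [list(map(float, tokens[i + 1 + k].split()))
                    for k in range(npts)]
            out["points"] = np.array(vals)
            i += 1 + npts
        elif key == "POLYGONS":
            ncells = int(parts[1])
            out["polygons"] = [list(map(int, tokens[i + 1 + k].split()))[1:]
                               for k in range(ncells)]
            i += 1 + ncells
        elif key == "SCALARS":
            name = parts[1]
            vals = [float(tokens[i + 2 + k]) for k in range(npts)]
            out["scalars"][name] = np.array(vals)
            i += 2 + npts
        elif key == "VECTORS":
            name = parts[1]
            vals = [list(map(float, tokens[i + 1 + k].split()))
                    for k in range(npts)]
            out["vectors"][name] = np.array(vals)
            i += 1 + npts
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# three-point radius of curvature
# ---------------------------------------------------------------------------

def circumradius_3pt(p1, p2, p3) -> float:
    """Radius of the unique circle through three planar points.

    Used to quantify device folding curvature from three points clicked on a
    micrograph.  Raises for (near-)collinear points.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    cross = ((p2[0] - p1[0]) * (p3[1] - p1[1])
             - (p2[1] - p1[1]) * (p3[0] - p1[0]))
    area = 0.5 * abs(cross)
    if area <= 1e-12 * max(a * b, b * c, a * c, 1e-300):
        raise ValueError("points are collinear: circle radius undefined")
    return a * b * c / (4.0 * area)
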