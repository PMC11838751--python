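"""Spherical geometry, RBF interpolation, CV fields and VTK export."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from shellmea.spheremap import (CVField, ElectrodeLayout, IsochroneMap3D,
                                RBFConfig, SphereGrid, build_isochrone,
                                circumradius_3pt, cv_field, export_vtk,
                                haversine, interpolate_lat, rbf_exact,
                                rbf_weight, read_vtk_polydata)

angles = st.floats(-math.pi / 2 + 0.01, math.pi / 2 - 0.01)
lons = st.floats(0.0, 2.0 * math.pi)


# ---------------------------------------------------------------------- #
# haversine
# ---------------------------------------------------------------------- #

@pytest.mark.parametrize("p1,p2,r,expected", [
    ((0.3, 1.2), (0.3, 1.2), 1.0, 0.0),                       # coincident
    ((0.0, 0.0), (0.0, math.pi), 1.0, math.pi),               # antipodal
    ((0.0, 0.0), (0.0, math.pi / 2), 0.025, 0.025 * math.pi / 2),
])
def test_haversine_reference_points(p1, p2, r, expected):
    assert haversine(p1[0], p1[1], p2[0], p2[1], r) == pytest.approx(expected)


@settings(derandomize=True, max_examples=100)
@given(angles, lons, angles, lons, angles, lons)
def test_haversine_metric_axioms(p1, l1, p2, l2, p3, l3):
    """Symmetry and the triangle inequality of the great-circle distance."""
    d12 = haversine(p1, l1, p2, l2)
    d21 = haversine(p2, l2, p1, l1)
    assert d12 == pytest.approx(d21, abs=1e-12)
    d13 = haversine(p1, l1, p3, l3)
    d23 = haversine(p2, l2, p3, l3)
    assert d13 <= d12 + d23 + 1e-9


def test_haversine_rejects_nonfinite():
    with pytest.raises(ValueError):
        haversine(np.nan, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------- #
# RBF weights and interpolation
# ---------------------------------------------------------------------- #

def test_rbf_weight_reference_values():
    eps = 0.37
    assert rbf_weight(0.0, eps) == 1.0
    assert rbf_weight(eps, eps) == pytest.approx(0.5)
    assert rbf_weight(3 * eps, eps) == pytest.approx(0.1)
    d = np.linspace(0, 10 * eps, 50)
    w = rbf_weight(d, eps)
    assert np.all(np.diff(w) < 0)          # strictly decreasing
    with pytest.raises(ValueError):
        rbf_weight(1.0, 0.0)


def _brute_force_interp(phi, lam, layout, node_lats, eps):
    """Direct scalar-loop evaluation of the weighted-mean rule, coded
    independently of the vectorized path."""
    num = den = 0.0
    for i in range(layout.n_electrodes):
        dphi = layout.phi[i] - phi
        dlam = layout.lam[i] - lam
        a = (math.sin(dphi / 2) ** 2
             + math.cos(phi) * math.cos(layout.phi[i]) * math.sin(dlam / 2) ** 2)
        d = 2 * layout.radius_cm * math.asin(math.sqrt(min(max(a, 0.0), 1.0)))
        w = 1.0 / (1.0 + (d / eps) ** 2)
        num += w * node_lats[i]
        den += w
    return num / den


def test_interpolation_matches_brute_force_oracle(layout):
    """Vectorized weighted-mean interpolation agrees with an independent
    scalar implementation to 1e-12 s on 1000 random query points."""
    rng = np.random.default_rng(42)
    node_lats = rng.uniform(0.0, 0.015, layout.n_electrodes)
    cfg = RBFConfig.for_layout(layout)
    phi = rng.uniform(-math.pi / 2, math.pi / 2, 1000)
    lam = rng.uniform(0, 2 * math.pi, 1000)
    vec = interpolate_lat(phi, lam, layout, node_lats, cfg)
    ref = np.array([_brute_force_interp(p, l, layout, node_lats, cfg.epsilon)
                    for p, l in zip(phi, lam)])
    assert np.max(np.abs(vec - ref)) < 1e-12


def test_interpolation_convex_combination_bound(layout):
    """Every interpolated value lies within [min, max] of the node LATs."""
    rng = np.random.default_rng(7)
    cfg = RBFConfig.for_layout(layout)
    grid = SphereGrid(16, 32)
    phi, lam = grid.mesh()
    for _ in range(200):
        node_lats = rng.uniform(-5, 5, layout.n_electrodes)
        vals = interpolate_lat(phi, lam, layout, node_lats, cfg)
        assert vals.min() >= node_lats.min() - 1e-12
        assert vals.max() <= node_lats.max() + 1e-12


def test_interpolation_constant_field(layout):
    cfg = RBFConfig.for_layout(layout)
    vals = interpolate_lat(np.array([0.1, -0.5]), np.array([1.0, 2.0]),
                           layout, np.full(16, 3.25e-3), cfg)
    assert vals == pytest.approx(3.25e-3)


def test_interpolation_two_node_symmetry():
    """A point equidistant from two nodes, with every other node much
    farther away, averages the two nearby LATs (weights decay as 1/d^2, so
    'much farther' must mean distance ratios >> 1)."""
    phi = np.zeros(16)
    lam = np.zeros(16)
    lam[0], lam[1] = -0.01, 0.01                 # the two near nodes
    phi[2:] = np.linspace(1.2, 1.5, 14)          # a remote cluster
    lam[2:] = np.pi
    layout = ElectrodeLayout(tuple(f"N{i}" for i in range(16)), phi, lam,
                             0.025)
    lats = np.full(16, 9.0)
    lats[0], lats[1] = 2.0, 4.0
    mid = interpolate_lat(0.0, 0.0, layout, lats, RBFConfig(1e-5))
    # the 1/d^2 tail of the 14 remote nodes still contributes ~0.1%
    assert mid == pytest.approx(3.0, abs=5e-3)


def test_small_eps_limit_reproduces_node_values_at_electrodes(layout):
    """As eps -> 0 the weighted mean evaluated AT an electrode approaches
    that electrode's LAT (its weight is 1 while all others vanish as
    eps^2 / d^2).  Away from the nodes the limit is inverse-square-distance
    Shepard weighting, not nearest-neighbor assignment."""
    rng = np.random.default_rng(3)
    node_lats = rng.uniform(0, 0.015, 16)
    cfg = RBFConfig(layout.radius_cm / 1000)
    at_nodes = interpolate_lat(layout.phi, layout.lam, layout, node_lats,
                               cfg)
    assert np.allclose(at_nodes, node_lats, atol=2e-5)


def test_interpolation_polar_rotation_equivariance(layout):
    """Rotating layout and query points together about the polar axis leaves
    interpolated values unchanged."""
    rng = np.random.default_rng(5)
    node_lats = rng.uniform(0, 0.015, 16)
    cfg = RBFConfig.for_layout(layout)
    phi = rng.uniform(-1.3, 1.3, 50)
    lam = rng.uniform(0, 2 * math.pi, 50)
    rot = 0.7317
    base = interpolate_lat(phi, lam, layout, node_lats, cfg)
    moved = interpolate_lat(phi, lam + rot, layout.rotated(rot), node_lats,
                            cfg)
    assert np.allclose(base, moved, atol=1e-12)


def test_exact_scheme_honors_electrode_values(layout):
    """The exact RBF interpolant passes through every electrode LAT; the
    weighted-mean smoother does not."""
    rng = np.random.default_rng(9)
    node_lats = rng.uniform(0, 0.015, 16)
    cfg = RBFConfig.for_layout(layout)
    at_nodes = rbf_exact(layout.phi, layout.lam, layout, node_lats, cfg)
    assert np.allclose(at_nodes, node_lats, atol=1e-12)
    smoothed = interpolate_lat(layout.phi, layout.lam, layout, node_lats, cfg)
    assert not np.allclose(smoothed, node_lats, atol=1e-6)


def test_interpolation_rejects_nonfinite_lats(layout):
    cfg = RBFConfig.for_layout(layout)
    bad = np.zeros(16)
    bad[3] = np.nan
    with pytest.raises(ValueError):
        interpolate_lat(0.0, 0.0, layout, bad, cfg)


# ---------------------------------------------------------------------- #
# isochrone map + CV field
# ---------------------------------------------------------------------- #

def test_isochrone_constant_input_gives_constant_map(layout):
    grid = SphereGrid(8, 16)
    iso = build_isochrone(layout, np.full(16, 2e-3), grid,
                          RBFConfig.for_layout(layout))
    assert np.allclose(iso.values, 2e-3)


def test_cv_field_meridional_wave_recovers_speed_everywhere():
    """T linear in latitude arc length (a pole-to-pole front at speed v):
    speed = v and direction = due south at every node, including the
    one-sided top/bottom rows."""
    v = 5.0
    r = 0.025
    grid = SphereGrid(32, 64)
    phi, _ = grid.mesh()
    iso = IsochroneMap3D(grid, (math.pi / 2 - phi) * r / v, r)
    fld = cv_field(iso)
    assert fld.valid.all()
    assert np.allclose(fld.speed, v, rtol=1e-9)
    assert np.allclose(fld.direction_north, -1.0, atol=1e-12)
    assert np.allclose(fld.direction_east, 0.0, atol=1e-12)


def test_cv_field_zonal_wave_shows_metric_factor():
    """T linear in longitude: the eastward arc-length gradient carries the
    1 / (r cos(phi)) metric factor, so speed = v cos(phi) exactly (wrap
    columns excluded where the longitude seam breaks linearity)."""
    v = 5.0
    r = 0.025
    grid = SphereGrid(16, 64)
    phi, lam = grid.mesh()
    iso = IsochroneMap3D(grid, lam * r / v, r)
    fld = cv_field(iso)
    interior = np.ones_like(phi, dtype=bool)
    interior[:, [0, -1]] = False           # longitude wrap seam
    sel = interior & fld.valid
    assert np.allclose(fld.speed[sel], (v * np.cos(phi))[sel], rtol=1e-9)
    assert np.allclose(fld.direction_east[sel], 1.0, atol=1e-12)


def test_cv_field_constant_map_fully_masked(layout):
    grid = SphereGrid(8, 16)
    iso = IsochroneMap3D(grid, np.full((8, 16), 1e-3), 0.025)
    with pytest.warns(UserWarning):
        fld = cv_field(iso)
    assert not fld.valid.any()
    assert np.all(np.isnan(fld.speed))


def test_cv_direction_vectors_are_unit_norm(layout):
    rng = np.random.default_rng(13)
    grid = SphereGrid(16, 32)
    iso = build_isochrone(layout, rng.uniform(0, 0.015, 16), grid,
                          RBFConfig.for_layout(layout))
    fld = cv_field(iso)
    norms = np.hypot(fld.direction_east, fld.direction_north)[fld.valid]
    assert np.allclose(norms, 1.0, atol=1e-12)
    assert np.all(fld.speed[fld.valid] > 0)


# ---------------------------------------------------------------------- #
# VTK export
# ---------------------------------------------------------------------- #

def test_vtk_round_trip_scalars_vectors_and_tangency(tmp_path, layout):
    rng = np.random.default_rng(21)
    grid = SphereGrid(12, 24)
    iso = build_isochrone(layout, rng.uniform(0, 0.015, 16), grid,
                          RBFConfig.for_layout(layout))
    fld = cv_field(iso)
    path = tmp_path / "map.vtk"
    export_vtk(path, isomap=iso, cvf=fld)
    d = read_vtk_polydata(path)
    assert d["points"].shape[0] == grid.n_lat * grid.n_lon
    assert np.allclose(d["scalars"]["LAT"], iso.values.ravel(),
                       rtol=0, atol=1e-9)
    radial = d["points"] / np.linalg.norm(d["points"], axis=1, keepdims=True)
    assert np.max(np.abs(np.sum(radial * d["vectors"]["CV"], axis=1))) < 1e-6


def test_vtk_requires_some_payload(tmp_path):
    with pytest.raises(ValueError):
        export_vtk(tmp_path / "x.vtk")


# ---------------------------------------------------------------------- #
# three-point radius of curvature
# ---------------------------------------------------------------------- #

@pytest.mark.parametrize("pts,expected", [
    ([(1, 0), (0, 1), (-1, 0)], 1.0),                  # unit circle
    ([(0, 0), (2, 0), (1, 1)], 1.0),                   # center (1, 0)
    ([(0, 0), (1, 0), (0.5, math.sqrt(3) / 2)], 1 / math.sqrt(3)),
])
def test_circumradius_known_circles(pts, expected):
    assert circumradius_3pt(*pts) == pytest.approx(expected)


def test_circumradius_collinear_points_rejected():
    with pytest.raises(ValueError):
        circumradius_3pt((0, 0), (1, 1), (2, 2))
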