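"""Voxelization, ray casting, contour extraction, precomputation, eligibility."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

import cinemv as cm
from cinemv.dicom_rt_io import CTGeometry, ROIContours
from cinemv.geometry import LinacGeometry, RoomPoint
from cinemv.roi_projection import (
    BinaryProjectionMap,
    ProjectionError,
    _RoomLattice,
    _round_half_away,
)


def _ct(dims=(32, 32, 16), spacing=(1.0, 1.0, 1.0), origin=None):
    rows, cols, slices = dims
    if origin is None:
        origin = (
            -(cols - 1) / 2.0 * spacing[1],
            -(rows - 1) / 2.0 * spacing[0],
            -(slices - 1) / 2.0 * spacing[2],
        )
    return CTGeometry(origin_mm=origin, spacing_mm=spacing, dims=dims)


def _square_roi(side_mm=10.0, z=0.0, center=(0.0, 0.0)):
    h = side_mm / 2.0
    cx, cy = center
    pts = np.array(
        [[cx - h, cy - h, z], [cx + h, cy - h, z], [cx + h, cy + h, z], [cx - h, cy + h, z]]
    )
    return ROIContours(name="sq", color=(255, 255, 0), contours=[pts])


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def test_voxelize_empty_roi_gives_zero_grid():
    grid = cm.voxelize_roi(ROIContours("empty", (1, 2, 3), []), _ct())
    assert not grid.occupancy.any()


def test_voxelize_square_matches_brute_force_point_in_polygon():
    ct = _ct(dims=(32, 32, 4), spacing=(1.0, 1.0, 1.0))
    roi = _square_roi(side_mm=10.0, z=ct.origin_mm[2] + 2.0, center=(0.3, -0.2))
    grid = cm.voxelize_roi(roi, ct)
    poly = Polygon(roi.contours[0][:, :2])
    expected = 0
    k = int(round((roi.contours[0][0, 2] - ct.origin_mm[2]) / ct.spacing_mm[2]))
    for i in range(ct.dims[0]):
        for j in range(ct.dims[1]):
            x, y, _ = ct.voxel_center_mm(i, j, k)
            inside = poly.contains(Point(x, y)) or poly.touches(Point(x, y))
            assert grid.occupancy[k, i, j] == inside
            expected += inside
    assert abs(int(grid.occupancy.sum()) - 100) <= 2 * 4 * 10 + 4  # perimeter rounding bound
    assert int(grid.occupancy.sum()) == expected


def test_voxelize_sphere_volume_close_to_analytic(bb_grid, bb_suite):
    spacing = bb_suite["ct"].spacing_mm
    vol = bb_grid.occupancy.sum() * spacing[0] * spacing[1] * spacing[2]
    assert vol == pytest.approx(4.0 / 3.0 * math.pi * 4.0**3, rel=0.10)


def test_voxelize_contour_outside_grid_rejected():
    ct = _ct(dims=(8, 8, 4))
    roi = _square_roi(z=100.0)
    with pytest.raises(ProjectionError):
        cm.voxelize_roi(roi, ct)


def test_voxelize_xor_combines_nested_contours_as_hole():
    ct = _ct(dims=(32, 32, 4))
    z = ct.origin_mm[2]
    outer = _square_roi(20.0, z).contours[0]
    inner = _square_roi(8.0, z).contours[0]
    roi = ROIContours("ring", (0, 0, 255), [outer, inner])
    grid = cm.voxelize_roi(roi, ct)
    k = 0
    assert not grid.occupancy[k, 16, 16]  # center voxel inside the hole
    assert grid.occupancy[k, 16, 7]  # within the ring band


# ---------------------------------------------------------------------------
# Dilation
# ---------------------------------------------------------------------------


def test_dilation_zero_radius_is_identity(bb_grid):
    out = cm.dilate_isotropic(bb_grid, 0.0)
    assert (out.occupancy == bb_grid.occupancy).all()


def test_dilation_single_voxel_sphere_count():
    ct = _ct(dims=(16, 16, 16))
    occ = np.zeros((16, 16, 16), dtype=bool)
    occ[8, 8, 8] = True
    grid = cm.VoxelGrid(ct, occ)
    out = cm.dilate_isotropic(grid, 5.0)
    # all voxels with center distance <= 5 mm of the seed (1 mm isotropic): 515
    assert int(out.occupancy.sum()) == 515


def test_dilation_monotone_and_respects_anisotropy(bb_grid):
    out = cm.dilate_isotropic(bb_grid, 2.0)
    assert (out.occupancy | bb_grid.occupancy).sum() == out.occupancy.sum()
    ct = _ct(dims=(9, 9, 9), spacing=(1.0, 1.0, 3.0))
    occ = np.zeros((9, 9, 9), dtype=bool)
    occ[4, 4, 4] = True
    out = cm.dilate_isotropic(cm.VoxelGrid(ct, occ), 3.0)
    assert out.occupancy[5, 4, 4] and out.occupancy[3, 4, 4]  # one 3-mm slice away
    assert not out.occupancy[6, 4, 4]  # 6 mm away


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


def test_raycast_empty_grid_gives_zero_map():
    ct = _ct()
    grid = cm.VoxelGrid(ct, np.zeros((16, 32, 32), dtype=bool))
    for theta in (0.0, 45.0, 90.0):
        assert not cm.raycast_projection(grid, theta, (0, 0, 0)).pixels.any()


def test_raycast_single_voxel_at_isocenter_covers_map_center():
    ct = _ct(dims=(17, 17, 9))
    occ = np.zeros((9, 17, 17), dtype=bool)
    occ[4, 8, 8] = True  # voxel centered at the isocenter
    grid = cm.VoxelGrid(ct, occ)
    for theta in np.arange(0.0, 360.0, 30.0):
        pm = cm.raycast_projection(grid, float(theta), (0, 0, 0))
        assert pm.pixels.any()
        rows, cols = np.nonzero(pm.pixels)
        assert rows.min() <= 255.5 <= rows.max() + 1
        assert cols.min() <= 255.5 <= cols.max() + 1


def test_raycast_sphere_disk_diameter(bb_grid, bb_suite):
    """8-mm sphere projects to a ~16-binned-pixel disk (0.5 mm at iso),
    scaled by the position-dependent projection factor."""
    iso = bb_suite["plan"].isocenter_mm
    for theta in (0.0, 90.0, 200.0, 275.5):
        pm = cm.raycast_projection(bb_grid, theta, iso)
        rows, cols = np.nonzero(pm.pixels)
        # projection scale for the BB position at this angle
        th = math.radians(theta)
        den = 100.0 - (-10.0 * math.sin(th) + 0.0 * math.cos(th))
        expected = 16.0 * (100.0 / den)
        assert cols.max() - cols.min() + 1 == pytest.approx(expected, abs=1.5)
        assert rows.max() - rows.min() + 1 == pytest.approx(expected, abs=1.5)


def _exact_slab_oracle(grid, theta, iso, geom):
    """Brute force: per pixel, ray/voxel-box (slab) intersection over every
    occupied voxel — exact 'ray meets any occupied voxel' semantics."""
    occ = grid.occupancy
    lat = _RoomLattice.from_ct(grid.geometry, iso)
    th = math.radians(theta)
    sin_t, cos_t = math.sin(th), math.cos(th)
    src = np.array([geom.sad_cm * sin_t, 0.0, geom.sad_cm * cos_t])
    u_hat = np.array([cos_t, 0.0, -sin_t])
    n_b = geom.panel_matrix // 2
    out = np.zeros((n_b, n_b), dtype=bool)
    ks, is_, js = np.nonzero(occ)
    # voxel box bounds in room coordinates, one row per occupied voxel
    xlo = np.minimum(lat.col_to_x(js - 0.5), lat.col_to_x(js + 0.5))
    xhi = np.maximum(lat.col_to_x(js - 0.5), lat.col_to_x(js + 0.5))
    ylo = np.minimum(lat.slice_to_y(ks - 0.5), lat.slice_to_y(ks + 0.5))
    yhi = np.maximum(lat.slice_to_y(ks - 0.5), lat.slice_to_y(ks + 0.5))
    zlo = np.minimum(lat.row_to_z(is_ - 0.5), lat.row_to_z(is_ + 0.5))
    zhi = np.maximum(lat.row_to_z(is_ - 0.5), lat.row_to_z(is_ + 0.5))

    def _pixel_hits(u, v):
        d = u * u_hat + np.array([0.0, v, 0.0]) - src
        t0 = np.zeros(xlo.shape)
        t1 = np.full(xlo.shape, geom.magnification)
        for dd, sc, lo, hi in ((d[0], src[0], xlo, xhi), (d[1], src[1], ylo, yhi), (d[2], src[2], zlo, zhi)):
            if abs(dd) < 1e-15:
                inside = (lo <= sc) & (sc <= hi)
                t0 = np.where(inside, t0, np.inf)
                continue
            ta, tb = (lo - sc) / dd, (hi - sc) / dd
            t0 = np.maximum(t0, np.minimum(ta, tb))
            t1 = np.minimum(t1, np.maximum(ta, tb))
        return bool((t1 >= t0).any())

    # candidate window: all rays through the padded occupied bounding box
    bxlo, bxhi = xlo.min(), xhi.max()
    bylo, byhi = ylo.min(), yhi.max()
    bzlo, bzhi = zlo.min(), zhi.max()
    cgrid = np.arange(n_b)
    u_all = ((2.0 * cgrid + 0.5) - 511.5) * 0.025
    v_all = u_all.copy()
    dirx = np.broadcast_to(u_all[None, :] * u_hat[0] - src[0], (n_b, n_b))
    diry = np.broadcast_to(v_all[:, None] - src[1], (n_b, n_b))
    dirz = np.broadcast_to(u_all[None, :] * u_hat[2] - src[2], (n_b, n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        T0 = np.zeros((n_b, n_b))
        T1 = np.full((n_b, n_b), geom.magnification)
        for dd, sc, lo, hi in (
            (dirx, src[0], bxlo, bxhi),
            (diry, src[1], bylo, byhi),
            (dirz, src[2], bzlo, bzhi),
        ):
            ta, tb = (lo - sc) / dd, (hi - sc) / dd
            tlo, thi = np.minimum(ta, tb), np.maximum(ta, tb)
            par = np.abs(dd) < 1e-12
            tlo = np.where(par, np.where((sc >= lo) & (sc <= hi), 0.0, np.inf), tlo)
            thi = np.where(par, np.where((sc >= lo) & (sc <= hi), geom.magnification, -np.inf), thi)
            T0, T1 = np.maximum(T0, tlo), np.minimum(T1, thi)
    for r, c in np.argwhere(T0 <= T1):
        out[r, c] = _pixel_hits(u_all[c], v_all[r])
    return out


def test_raycast_equals_exact_ray_voxel_oracle():
    """Pixelwise equality with a brute-force ray/voxel intersection oracle
    on a small grid, at axis-aligned and oblique angles."""
    ct = _ct(dims=(12, 12, 6), spacing=(1.0, 1.0, 2.0), origin=(-25.5, -5.5, -5.0))
    occ = np.zeros((6, 12, 12), dtype=bool)
    occ[2:4, 4:9, 3:8] = True  # small off-axis cuboid
    occ[3, 6, 9] = True  # plus a protruding voxel
    grid = cm.VoxelGrid(ct, occ)
    geom = LinacGeometry()
    for theta in (0.0, 37.3, 90.0, 211.7, 301.9):
        pm = cm.raycast_projection(grid, theta, (0.0, 0.0, 0.0), geom)
        oracle = _exact_slab_oracle(grid, theta, (0.0, 0.0, 0.0), geom)
        assert (pm.pixels == oracle).all(), f"mismatch at theta={theta}"


def test_raycast_equals_exact_oracle_on_bb_sphere(bb_grid, bb_suite):
    geom = LinacGeometry()
    iso = bb_suite["plan"].isocenter_mm
    for theta in (90.0, 211.7):
        pm = cm.raycast_projection(bb_grid, theta, iso, geom)
        oracle = _exact_slab_oracle(bb_grid, theta, iso, geom)
        assert (pm.pixels == oracle).all(), f"mismatch at theta={theta}"


def test_translated_roi_moves_centroid_as_projection_predicts(bb_suite):
    """Translating the ROI laterally moves the projected centroid by the
    central-projection prediction, within one binned pixel."""
    ct = bb_suite["ct"]
    iso = bb_suite["plan"].isocenter_mm
    roi = bb_suite["structures"]["BB"]
    shifted = ROIContours(
        name="BBs", color=roi.color, contours=[c + np.array([4.0, 0.0, 0.0]) for c in roi.contours]
    )
    g0 = cm.voxelize_roi(roi, ct)
    g1 = cm.voxelize_roi(shifted, ct)
    for theta in (0.0, 140.0, 320.5):
        c0 = cm.extract_contour(cm.raycast_projection(g0, theta, iso)).centroid
        c1 = cm.extract_contour(cm.raycast_projection(g1, theta, iso)).centroid
        p0 = cm.project_point(RoomPoint(-10.0, -5.0, 0.0), theta)
        p1 = cm.project_point(RoomPoint(-9.6, -5.0, 0.0), theta)
        pred_cols = (p1.u_cm - p0.u_cm) * 10.0 / 0.5
        pred_rows = (p1.v_cm - p0.v_cm) * 10.0 / 0.5
        assert c1[0] - c0[0] == pytest.approx(pred_cols, abs=1.0)
        assert c1[1] - c0[1] == pytest.approx(pred_rows, abs=1.0)


def test_convex_projection_has_no_holes(bb_grid, bb_suite):
    from scipy import ndimage

    pm = cm.raycast_projection(bb_grid, 73.5, bb_suite["plan"].isocenter_mm)
    filled = ndimage.binary_fill_holes(pm.pixels)
    assert (filled == pm.pixels).all()


# ---------------------------------------------------------------------------
# Contour extraction
# ---------------------------------------------------------------------------


def _brute_force_boundary(mask):
    h, w = mask.shape
    out = np.zeros_like(mask)
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            if r in (0, h - 1) or c in (0, w - 1):
                out[r, c] = True
                continue
            neigh = mask[r - 1 : r + 2, c - 1 : c + 2]
            if (~neigh).sum() > 0:
                out[r, c] = True
    return out


def test_contour_single_pixel_is_its_own_boundary():
    m = np.zeros((512, 512), dtype=bool)
    m[100, 200] = True
    ov = cm.extract_contour(BinaryProjectionMap(m, 0.0))
    assert ov.boundary_pixels.tolist() == [[200, 100]]
    assert ov.centroid == (200.0, 100.0)


def test_contour_solid_block_perimeter():
    m = np.zeros((512, 512), dtype=bool)
    m[10:13, 20:23] = True
    ov = cm.extract_contour(BinaryProjectionMap(m, 0.0))
    assert len(ov.boundary_pixels) == 8  # 3x3 block minus its center
    assert ov.centroid == (21.0, 11.0)


def test_contour_all_ones_map_keeps_border_only():
    m = np.ones((64, 64), dtype=bool)
    ov = cm.extract_contour(BinaryProjectionMap(m, 0.0))
    assert len(ov.boundary_pixels) == 4 * 64 - 4


def test_contour_matches_brute_force_8_neighbor_scan(rng):
    for _ in range(10):
        m = rng.random((24, 24)) < 0.35
        ov = cm.extract_contour(BinaryProjectionMap(m, 0.0))
        expected = _brute_force_boundary(m)
        got = np.zeros_like(m)
        if not ov.empty:
            got[ov.boundary_pixels[:, 1], ov.boundary_pixels[:, 0]] = True
        assert (got == expected).all()


def test_contour_empty_map_flagged():
    ov = cm.extract_contour(BinaryProjectionMap(np.zeros((512, 512), dtype=bool), 0.0))
    assert ov.empty and ov.centroid is None


def test_contour_idempotent_on_reconstructed_boundary(bb_grid, bb_suite):
    pm = cm.raycast_projection(bb_grid, 45.0, bb_suite["plan"].isocenter_mm)
    ov = cm.extract_contour(pm)
    mask = np.zeros_like(pm.pixels)
    mask[ov.boundary_pixels[:, 1], ov.boundary_pixels[:, 0]] = True
    ov2 = cm.extract_contour(BinaryProjectionMap(mask, 45.0))
    # every pixel of a thin boundary is itself boundary
    assert sorted(map(tuple, ov2.boundary_pixels)) == sorted(map(tuple, ov.boundary_pixels))


# ---------------------------------------------------------------------------
# Precomputed set + lookup
# ---------------------------------------------------------------------------


def test_precompute_has_720_overlays_and_matches_on_the_fly(bb_pset, bb_grid, bb_suite):
    ovs = bb_pset.overlays["BB"]
    assert len(ovs) == 720
    for theta in (0.0, 123.5, 250.0):
        idx = int(theta / 0.5)
        direct = cm.extract_contour(
            cm.raycast_projection(bb_grid, theta, bb_suite["plan"].isocenter_mm),
            bb_suite["structures"]["BB"].color,
        )
        assert ovs[idx].centroid == pytest.approx(direct.centroid)
        assert sorted(map(tuple, ovs[idx].boundary_pixels)) == sorted(
            map(tuple, direct.boundary_pixels)
        )


def test_projection_set_roundtrip_lossless(bb_pset, tmp_path):
    p = tmp_path / "pset.json"
    bb_pset.save(p)
    loaded = cm.ProjectionSet.load(p)
    for a, b in zip(bb_pset.overlays["BB"], loaded.overlays["BB"]):
        assert a.centroid == b.centroid
        assert (a.boundary_pixels == b.boundary_pixels).all()
        assert a.color == b.color


def test_lookup_overlay_nearest_and_wrapping(bb_pset):
    assert cm.lookup_overlay(bb_pset, "BB", 10.0).theta_deg == 10.0
    assert cm.lookup_overlay(bb_pset, "BB", 10.24).theta_deg == 10.0
    assert cm.lookup_overlay(bb_pset, "BB", 10.26).theta_deg == 10.5
    assert cm.lookup_overlay(bb_pset, "BB", 10.25).theta_deg == 10.0  # tie -> lower
    assert cm.lookup_overlay(bb_pset, "BB", 359.9).theta_deg == 0.0
    with pytest.raises(KeyError):
        cm.lookup_overlay(bb_pset, "nope", 0.0)


# ---------------------------------------------------------------------------
# Field eligibility
# ---------------------------------------------------------------------------


def _plan_with_field(tmp_path, field_mm):
    spec = cm.FixtureSpec.bb_validation(seed=2, field_size_mm=field_mm)
    paths = cm.write_fixture_suite(spec, tmp_path)
    return cm.read_plan(paths["rtplan"])


def test_field_10cm_passes(tmp_path):
    plan = _plan_with_field(tmp_path, 100.0)
    report = cm.field_within_epid(plan, margin_mm=5.0)
    assert report["eligible"]


def test_field_24cm_passes_with_5mm_margin(tmp_path):
    plan = _plan_with_field(tmp_path, 240.0)
    assert cm.field_within_epid(plan, margin_mm=5.0)["eligible"]


def test_field_26cm_fails(tmp_path):
    plan = _plan_with_field(tmp_path, 260.0)
    report = cm.field_within_epid(plan, margin_mm=5.0)
    assert not report["eligible"]
    assert any(
        not cp["pass"] for b in report["beams"] for cp in b["control_points"]
    )


def test_collimator_rotation_expands_corner_extent(tmp_path):
    # a 24 cm square rotated 45 deg has corners at 24*sqrt(2)/2 = 17 cm > 12.8 cm
    spec = cm.FixtureSpec.bb_validation(seed=2, field_size_mm=240.0)
    spec.arcs = [cm.ArcBeamSpec(speed_deg_s=1.5, field_size_mm=240.0, collimator_deg=45.0)]
    paths = cm.write_fixture_suite(spec, tmp_path)
    plan = cm.read_plan(paths["rtplan"])
    assert not cm.field_within_epid(plan, margin_mm=5.0)["eligible"]
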