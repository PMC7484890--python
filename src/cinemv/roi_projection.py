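"""Beam's-eye-view ROI projection onto the virtual portal imager.

The projection pipeline voxelizes RTSTRUCT contours on the planning-CT
lattice, then for every gantry angle casts one ray per 2x2 detector-element
group from the source through the panel and tests, at each lattice plane of
the occupied region, whether the nearest voxel (nearest-integer index at the
plane crossing) is inside the ROI.  A pixel whose ray meets any occupied
voxel is set in a 512 x 512 binary map; the contour is the set of map pixels
with value 1 that touch a zero 8-neighbor or the map border.  Projections
are precomputed on a 0.5-degree grid over the full rotation and serialized
so that nothing expensive runs at treatment time.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .dicom_rt_io import (
    CTGeometry,
    PlanInfo,
    ROIContours,
    StructureSet,
)
from .geometry import LinacGeometry, RoomPoint, project_point, reduce_angle

__all__ = [
    "ProjectionError",
    "VoxelGrid",
    "BinaryProjectionMap",
    "ContourOverlay",
    "ProjectionSet",
    "voxelize_roi",
    "dilate_isotropic",
    "raycast_projection",
    "extract_contour",
    "precompute_set",
    "lookup_overlay",
    "field_within_epid",
]

_FORMAT_VERSION = 1


class ProjectionError(ValueError):
    pass


@dataclass
class VoxelGrid:
    """Binary occupancy on the planning-CT lattice.

    ``occupancy[slice, row, col]`` is True inside the ROI.  Voxel centers
    coincide with the CT lattice points of :class:`CTGeometry`.
    """

    geometry: CTGeometry
    occupancy: np.ndarray

    def __post_init__(self) -> None:
        expected = (self.geometry.dims[2], self.geometry.dims[0], self.geometry.dims[1])
        if tuple(self.occupancy.shape) != expected:
            raise ProjectionError(
                f"occupancy shape {self.occupancy.shape} != (slices, rows, cols) {expected}"
            )
        self.occupancy = self.occupancy.astype(bool)


@dataclass
class BinaryProjectionMap:
    pixels: np.ndarray  # (512, 512) bool, [row, col]
    theta_deg: float
    roi_name: str = ""


@dataclass
class ContourOverlay:
    """Boundary pixels + mass centroid of one ROI projection at one angle.

    Pixel coordinates are (column, row) at binned (512) resolution; the
    centroid is that of the *filled* projection, not of the boundary.
    An empty projection has no pixels and ``centroid is None``.
    """

    boundary_pixels: np.ndarray  # (N, 2) int, columns (col, row)
    centroid: tuple[float, float] | None
    color: tuple[int, int, int]
    theta_deg: float = 0.0
    roi_name: str = ""

    @property
    def empty(self) -> bool:
        return self.boundary_pixels.shape[0] == 0


@dataclass
class ProjectionSet:
    """Per-ROI overlays on the regular angle grid (720 entries at 0.5 deg)."""

    angle_step_deg: float
    overlays: dict[str, list[ContourOverlay]]
    provenance: dict = field(default_factory=dict)

    @property
    def n_angles(self) -> int:
        return int(round(360.0 / self.angle_step_deg))

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": _FORMAT_VERSION,
            "angle_step_deg": self.angle_step_deg,
            "provenance": self.provenance,
            "rois": {
                name: [
                    {
                        "theta_deg": ov.theta_deg,
                        "boundary_pixels": ov.boundary_pixels.tolist(),
                        "centroid": list(ov.centroid) if ov.centroid is not None else None,
                        "color": list(ov.color),
                    }
                    for ov in ovs
                ]
                for name, ovs in self.overlays.items()
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionSet":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != _FORMAT_VERSION:
            raise ProjectionError(f"unsupported projection-set version: {doc.get('format_version')}")
        overlays = {
            name: [
                ContourOverlay(
                    boundary_pixels=np.asarray(item["boundary_pixels"], dtype=int).reshape(-1, 2),
                    centroid=tuple(item["centroid"]) if item["centroid"] is not None else None,
                    color=tuple(item["color"]),
                    theta_deg=item["theta_deg"],
                    roi_name=name,
                )
                for item in items
            ]
            for name, items in doc["rois"].items()
        }
        return cls(
            angle_step_deg=float(doc["angle_step_deg"]),
            overlays=overlays,
            provenance=doc.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Voxelization
# ---------------------------------------------------------------------------


def _even_odd_inside(px: np.ndarray, py: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd (ray crossing) test; boundary vertices are inside."""
    inside = np.zeros(px.shape, dtype=bool)
    n = poly.shape[0]
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > py) != (y2 > py)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (px < xint)
    # Boundary vertices count as inside.
    for x1, y1 in poly:
        inside |= (np.abs(px - x1) < 1e-9) & (np.abs(py - y1) < 1e-9)
    return inside


def voxelize_roi(roi: ROIContours, ct: CTGeometry) -> VoxelGrid:
    """Slice-wise even-odd polygon fill of planar contours at voxel centers.

    Multiple contours on one slice combine by exclusive-or, so ring-shaped
    structures voxelize with holes.
    """
    rows, cols, slices = ct.dims
    occ = np.zeros((slices, rows, cols), dtype=bool)
    ox, oy, oz = ct.origin_mm
    sr, sc, ss = ct.spacing_mm
    xs = ox + np.arange(cols) * sc
    ys = oy + np.arange(rows) * sr
    for pts in roi.contours:
        z = pts[0, 2]
        k = int(round((z - oz) / ss))
        if not (0 <= k < slices):
            raise ProjectionError(f"ROI {roi.name!r}: contour at z={z:.2f} mm outside the grid")
        poly = pts[:, :2]
        jmin = max(0, int(np.floor((poly[:, 0].min() - ox) / sc)))
        jmax = min(cols - 1, int(np.ceil((poly[:, 0].max() - ox) / sc)))
        imin = max(0, int(np.floor((poly[:, 1].min() - oy) / sr)))
        imax = min(rows - 1, int(np.ceil((poly[:, 1].max() - oy) / sr)))
        if jmin > jmax or imin > imax:
            continue
        px, py = np.meshgrid(xs[jmin : jmax + 1], ys[imin : imax + 1])
        occ[k, imin : imax + 1, jmin : jmax + 1] ^= _even_odd_inside(px, py, poly)
    return VoxelGrid(geometry=ct, occupancy=occ)


def dilate_isotropic(grid: VoxelGrid, radius_mm: float) -> VoxelGrid:
    """Physical-distance isotropic dilation (spherical structuring element
    respecting anisotropic voxel spacing)."""
    if radius_mm < 0:
        raise ProjectionError("dilation radius must be >= 0")
    if radius_mm == 0:
        return VoxelGrid(grid.geometry, grid.occupancy.copy())
    sr, sc, ss = grid.geometry.spacing_mm
    nk = int(radius_mm / ss)
    ni = int(radius_mm / sr)
    nj = int(radius_mm / sc)
    dk, di, dj = np.meshgrid(
        np.arange(-nk, nk + 1) * ss,
        np.arange(-ni, ni + 1) * sr,
        np.arange(-nj, nj + 1) * sc,
        indexing="ij",
    )
    ball = dk**2 + di**2 + dj**2 <= radius_mm**2 + 1e-9
    return VoxelGrid(grid.geometry, ndimage.binary_dilation(grid.occupancy, structure=ball))


# ---------------------------------------------------------------------------
# Ray casting
# ---------------------------------------------------------------------------


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


@dataclass(frozen=True)
class _RoomLattice:
    """Affine maps between voxel indices and room coordinates (cm)."""

    x0: float  # room X of col 0
    dx: float  # per col
    y0: float  # room Y of slice 0
    dy: float  # per slice
    z0: float  # room Z of row 0
    dz: float  # per row (negative: +row is posterior = downward)

    @classmethod
    def from_ct(cls, ct: CTGeometry, isocenter_mm: Sequence[float]) -> "_RoomLattice":
        ox, oy, oz = ct.origin_mm
        sr, sc, ss = ct.spacing_mm
        ix, iy, iz = (float(v) for v in isocenter_mm)
        return cls(
            x0=(ox - ix) / 10.0,
            dx=sc / 10.0,
            y0=(oz - iz) / 10.0,
            dy=ss / 10.0,
            z0=-(oy - iy) / 10.0,
            dz=-sr / 10.0,
        )

    def col_to_x(self, j: np.ndarray) -> np.ndarray:
        return self.x0 + j * self.dx

    def slice_to_y(self, k: np.ndarray) -> np.ndarray:
        return self.y0 + k * self.dy

    def row_to_z(self, i: np.ndarray) -> np.ndarray:
        return self.z0 + i * self.dz

    def x_to_col(self, x: np.ndarray) -> np.ndarray:
        return (x - self.x0) / self.dx

    def y_to_slice(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y0) / self.dy

    def z_to_row(self, z: np.ndarray) -> np.ndarray:
        return (z - self.z0) / self.dz


def raycast_projection(
    grid: VoxelGrid,
    theta_deg: float,
    isocenter_mm: Sequence[float],
    geom: LinacGeometry | None = None,
    roi_name: str = "",
) -> BinaryProjectionMap:
    """Binary beam's-eye-view projection of a voxel grid at one gantry angle.

    One ray per 2x2 detector group, from the source through the center of
    the group on an ideal flat panel at SDD.  At every lattice plane of the
    occupied bounding region the ray crossing is rounded to the nearest
    voxel index (half away from zero); the pixel is set as soon as any
    crossing lands in an occupied voxel.  Only crossings on the source-to-
    panel segment count.  The result is order-independent, so planes are
    evaluated vectorized over pixels.
    """
    geom = geom or LinacGeometry()
    n_b = geom.panel_matrix // 2
    pixels = np.zeros((n_b, n_b), dtype=bool)
    occ = grid.occupancy
    if not occ.any():
        return BinaryProjectionMap(pixels=pixels, theta_deg=theta_deg, roi_name=roi_name)

    lat = _RoomLattice.from_ct(grid.geometry, isocenter_mm)
    ks, is_, js = np.nonzero(occ)
    kmin, kmax = ks.min(), ks.max()
    imin, imax = is_.min(), is_.max()
    jmin, jmax = js.min(), js.max()

    th = math.radians(reduce_angle(theta_deg))
    sin_t, cos_t = math.sin(th), math.cos(th)
    sad = geom.sad_cm
    src = np.array([sad * sin_t, 0.0, sad * cos_t])

    # Candidate pixel window: project the padded corners of the occupied box.
    cols_rng, rows_rng = [], []
    pitch_b = 2.0 * geom.pixel_iso_mm
    for k in (kmin - 1, kmax + 1):
        for i in (imin - 1, imax + 1):
            for j in (jmin - 1, jmax + 1):
                p = RoomPoint(
                    float(lat.col_to_x(j)), float(lat.slice_to_y(k)), float(lat.row_to_z(i))
                )
                res = project_point(p, theta_deg, geom)
                u_mm, v_mm = 10.0 * res.u_cm, 10.0 * res.v_cm
                cols_rng.append((n_b / 2.0 - 0.5) + u_mm / pitch_b)
                rows_rng.append((n_b / 2.0 - 0.5) + v_mm / pitch_b)
    c_lo = max(0, int(np.floor(min(cols_rng))) - 2)
    c_hi = min(n_b - 1, int(np.ceil(max(cols_rng))) + 2)
    r_lo = max(0, int(np.floor(min(rows_rng))) - 2)
    r_hi = min(n_b - 1, int(np.ceil(max(rows_rng))) + 2)
    if c_lo > c_hi or r_lo > r_hi:
        return BinaryProjectionMap(pixels=pixels, theta_deg=theta_deg, roi_name=roi_name)

    cgrid = np.arange(c_lo, c_hi + 1)
    rgrid = np.arange(r_lo, r_hi + 1)
    # Ray target: the pixel position expressed on the isocenter plane (same
    # line as through the physical panel position at SDD).
    u_cm = ((2.0 * cgrid + 0.5) - (geom.panel_matrix / 2.0 - 0.5)) * geom.pixel_iso_mm / 10.0
    v_cm = ((2.0 * rgrid + 0.5) - (geom.panel_matrix / 2.0 - 0.5)) * geom.pixel_iso_mm / 10.0
    u_hat = np.array([cos_t, 0.0, -sin_t])
    v_hat = np.array([0.0, 1.0, 0.0])
    # direction = iso_point - src, per (row, col) pixel
    dir_x = u_cm[None, :] * u_hat[0] - src[0]
    dir_y = np.broadcast_to(v_cm[:, None], (rgrid.size, cgrid.size)) - src[1]
    dir_z = u_cm[None, :] * u_hat[2] - src[2]

    hit = np.zeros((rgrid.size, cgrid.size), dtype=bool)
    t_max = geom.magnification  # t=1 at the isocenter plane, SDD/SAD at the panel

    # Lattice planes are taken at the voxel boundaries of each occupied
    # layer, so every voxel the ray traverses produces a crossing on one of
    # its faces: the crossing coordinate sits exactly between two voxel
    # indices (the nearest-integer tie), and both neighbors of the crossed
    # layer are tested with the remaining indices rounded.  This makes the
    # first-hit test exact (pixel = 1 iff the ray meets an occupied voxel).
    def _test_boundary(t: np.ndarray, axis: str, lo_idx: int) -> None:
        valid = np.isfinite(t) & (t > 0.0) & (t <= t_max) & ~hit
        if not valid.any():
            return
        x = src[0] + t * dir_x
        y = src[1] + t * dir_y
        z = src[2] + t * dir_z
        if axis == "col":
            pair = (lo_idx, lo_idx + 1)
            kk = _round_half_away(lat.y_to_slice(y))
            ii = _round_half_away(lat.z_to_row(z))
            others_ok = (kk >= 0) & (kk < occ.shape[0]) & (ii >= 0) & (ii < occ.shape[1])
            kk_c = np.clip(kk, 0, occ.shape[0] - 1)
            ii_c = np.clip(ii, 0, occ.shape[1] - 1)
            for j in pair:
                if 0 <= j < occ.shape[2]:
                    hit[:] |= valid & others_ok & occ[kk_c, ii_c, j]
        elif axis == "slice":
            pair = (lo_idx, lo_idx + 1)
            jj = _round_half_away(lat.x_to_col(x))
            ii = _round_half_away(lat.z_to_row(z))
            others_ok = (jj >= 0) & (jj < occ.shape[2]) & (ii >= 0) & (ii < occ.shape[1])
            jj_c = np.clip(jj, 0, occ.shape[2] - 1)
            ii_c = np.clip(ii, 0, occ.shape[1] - 1)
            for k in pair:
                if 0 <= k < occ.shape[0]:
                    hit[:] |= valid & others_ok & occ[k, ii_c, jj_c]
        else:  # row
            pair = (lo_idx, lo_idx + 1)
            jj = _round_half_away(lat.x_to_col(x))
            kk = _round_half_away(lat.y_to_slice(y))
            others_ok = (jj >= 0) & (jj < occ.shape[2]) & (kk >= 0) & (kk < occ.shape[0])
            jj_c = np.clip(jj, 0, occ.shape[2] - 1)
            kk_c = np.clip(kk, 0, occ.shape[0] - 1)
            for i in pair:
                if 0 <= i < occ.shape[1]:
                    hit[:] |= valid & others_ok & occ[kk_c, i, jj_c]

    with np.errstate(divide="ignore", invalid="ignore"):
        # Boundary planes of constant room X (between CT columns).
        for j in range(jmin - 1, jmax + 1):
            plane = lat.col_to_x(j + 0.5)
            _test_boundary((plane - src[0]) / dir_x, "col", j)
        # Boundary planes of constant room Y (between CT slices).
        for k in range(kmin - 1, kmax + 1):
            plane = lat.slice_to_y(k + 0.5)
            _test_boundary((plane - src[1]) / dir_y, "slice", k)
        # Boundary planes of constant room Z (between CT rows).
        for i in range(imin - 1, imax + 1):
            plane = lat.row_to_z(i + 0.5)
            _test_boundary((plane - src[2]) / dir_z, "row", i)

    pixels[r_lo : r_hi + 1, c_lo : c_hi + 1] = hit
    return BinaryProjectionMap(pixels=pixels, theta_deg=theta_deg, roi_name=roi_name)


# ---------------------------------------------------------------------------
# Contours
# ---------------------------------------------------------------------------


def extract_contour(
    pmap: BinaryProjectionMap, color: tuple[int, int, int] = (255, 0, 0)
) -> ContourOverlay:
    """Boundary pixels (zero 8-neighbor or map border) + filled-map centroid."""
    mask = pmap.pixels.astype(bool)
    if not mask.any():
        return ContourOverlay(
            boundary_pixels=np.empty((0, 2), dtype=int),
            centroid=None,
            color=color,
            theta_deg=pmap.theta_deg,
            roi_name=pmap.roi_name,
        )
    interior = ndimage.binary_erosion(mask, structure=np.ones((3, 3), dtype=bool), border_value=0)
    boundary = mask & ~interior
    rows, cols = np.nonzero(boundary)
    frows, fcols = np.nonzero(mask)
    centroid = (float(fcols.mean()), float(frows.mean()))
    return ContourOverlay(
        boundary_pixels=np.column_stack([cols, rows]).astype(int),
        centroid=centroid,
        color=color,
        theta_deg=pmap.theta_deg,
        roi_name=pmap.roi_name,
    )


# ---------------------------------------------------------------------------
# Precomputation and lookup
# ---------------------------------------------------------------------------


def precompute_set(
    rois: StructureSet,
    plan: PlanInfo,
    ct: CTGeometry,
    geom: LinacGeometry | None = None,
    roi_names: Sequence[str] | None = None,
    margin_mm: float = 0.0,
) -> ProjectionSet:
    """Precompute contour overlays for every grid angle (0.5 deg over 360).

    ``margin_mm`` optionally applies an isotropic expansion to each ROI
    before projection (tolerance margins for motion monitoring).
    """
    geom = geom or LinacGeometry()
    names = list(roi_names) if roi_names is not None else rois.names
    if not names:
        raise ProjectionError("no ROI selected for precomputation")
    angles = geom.angle_grid_deg
    overlays: dict[str, list[ContourOverlay]] = {}
    for name in names:
        roi = rois[name]
        try:
            grid = voxelize_roi(roi, ct)
            if margin_mm > 0:
                grid = dilate_isotropic(grid, margin_mm)
            ovs = []
            for theta in angles:
                pmap = raycast_projection(grid, float(theta), plan.isocenter_mm, geom, name)
                ovs.append(extract_contour(pmap, roi.color))
        except ProjectionError as exc:
            raise ProjectionError(f"ROI {name!r}: {exc}") from exc
        overlays[name] = ovs
    return ProjectionSet(
        angle_step_deg=geom.angle_step_deg,
        overlays=overlays,
        provenance={"plan_label": plan.label, "rois": names, "margin_mm": margin_mm},
    )


def lookup_index(pset: ProjectionSet, theta_deg: float) -> int:
    """Grid index of the angle nearest theta, wrap-aware, ties toward the
    lower grid angle."""
    step = pset.angle_step_deg
    return int(math.ceil(reduce_angle(theta_deg) / step - 0.5)) % pset.n_angles


def lookup_overlay(pset: ProjectionSet, roi_name: str, theta_deg: float) -> ContourOverlay:
    """Overlay at the grid angle nearest theta, wrap-aware, ties to the lower
    grid angle."""
    if roi_name not in pset.overlays:
        raise KeyError(f"unknown ROI {roi_name!r}")
    return pset.overlays[roi_name][lookup_index(pset, theta_deg)]


# ---------------------------------------------------------------------------
# Field eligibility
# ---------------------------------------------------------------------------


def field_within_epid(
    plan: PlanInfo,
    geom: LinacGeometry | None = None,
    margin_mm: float = 5.0,
) -> dict:
    """Check every control point's primary field against the imager area.

    A control point fails when any aperture vertex (per-leaf open rectangles
    clipped by the jaws, rotated by the collimator angle, expanded by the
    security margin) exceeds the field of view at isocenter.  Returns a
    report with per-beam, per-control-point pass/fail and an overall flag.
    """
    geom = geom or LinacGeometry()
    half_fov = 10.0 * geom.fov_iso_cm / 2.0
    report: dict = {"margin_mm": margin_mm, "beams": [], "eligible": True}
    for beam in plan.beams:
        bounds = beam.leaf_boundaries_mm
        cp_rows = []
        for icp, cp in enumerate(beam.control_points):
            verts: list[tuple[float, float]] = []
            x_lo, x_hi = cp.jaw_x_mm
            y_lo, y_hi = cp.jaw_y_mm
            for a, b, lo, hi in zip(
                cp.mlc_bank_a_mm, cp.mlc_bank_b_mm, bounds[:-1], bounds[1:]
            ):
                xa, xb = max(a, x_lo), min(b, x_hi)
                ya, yb = max(lo, y_lo), min(hi, y_hi)
                if xb <= xa or yb <= ya:
                    continue
                verts.extend([(xa, ya), (xa, yb), (xb, ya), (xb, yb)])
            if not verts:
                cp_rows.append({"index": icp, "gantry_deg": cp.gantry_deg, "pass": True})
                continue
            phi = math.radians(cp.collimator_deg)
            c, s = math.cos(phi), math.sin(phi)
            worst = 0.0
            for vx, vy in verts:
                rx, ry = c * vx - s * vy, s * vx + c * vy
                worst = max(worst, abs(rx), abs(ry))
            ok = worst + margin_mm <= half_fov + 1e-9
            cp_rows.append(
                {"index": icp, "gantry_deg": cp.gantry_deg, "pass": ok, "extent_mm": worst}
            )
            if not ok:
                report["eligible"] = False
        report["beams"].append({"beam": beam.name, "control_points": cp_rows})
    return report
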