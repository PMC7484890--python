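"""Reading planning DICOM objects and writing minimal synthetic fixtures.

Three readers cover what the projection pipeline needs: the CT lattice
(geometry only), the RTSTRUCT planar contours, and the RTPLAN isocenter and
control points.  A fixture writer produces minimal but toolkit-readable CT /
RTSTRUCT / RTPLAN files for analytically defined phantoms (spheres and
cylinders), standing in for a treatment-planning-system export.

Coordinate bridge.  The patient frame is the DICOM patient coordinate
system; the room frame has its origin at the plan isocenter with

    room X (lateral, cm)      = (patient x - iso x) / 10
    room Y (longitudinal, cm) = (patient z - iso z) / 10
    room Z (vertical, cm)     = -(patient y - iso y) / 10

assuming identity (head-first supine) orientation, the only orientation
supported.  Fixtures are generated in the same convention, so the bridge is
self-consistent and testable end to end.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

__all__ = [
    "DicomIOError",
    "CTGeometry",
    "ROIContours",
    "StructureSet",
    "ControlPoint",
    "PlanBeam",
    "PlanInfo",
    "FixtureSpec",
    "SphereROI",
    "CylinderROI",
    "ArcBeamSpec",
    "read_ct_geometry",
    "read_structure_set",
    "read_plan",
    "write_fixture_suite",
    "patient_to_room_cm",
    "room_to_patient_mm",
]

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
_RTPLAN_SOP = "1.2.840.10008.5.1.4.1.1.481.5"
_SLICE_SPACING_TOL_MM = 0.01


class DicomIOError(ValueError):
    pass


# ---------------------------------------------------------------------------
# In-memory types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CTGeometry:
    """Planning-CT lattice: origin of the first voxel (mm, patient frame),
    (row, column, slice) spacing in mm, (rows, columns, slices) counts and
    direction cosines (identity orientation only)."""

    origin_mm: tuple[float, float, float]
    spacing_mm: tuple[float, float, float]
    dims: tuple[int, int, int]
    orientation: tuple[float, ...] = (1, 0, 0, 0, 1, 0)

    def voxel_center_mm(self, row: int, col: int, slc: int) -> tuple[float, float, float]:
        ox, oy, oz = self.origin_mm
        sr, sc, ss = self.spacing_mm
        return (ox + col * sc, oy + row * sr, oz + slc * ss)

    @property
    def slice_positions_mm(self) -> np.ndarray:
        return self.origin_mm[2] + np.arange(self.dims[2]) * self.spacing_mm[2]


@dataclass
class ROIContours:
    name: str
    color: tuple[int, int, int]
    contours: list[np.ndarray]  # each (N, 3) patient mm, closed planar polygon


@dataclass
class StructureSet:
    rois: list[ROIContours]

    def __getitem__(self, name: str) -> ROIContours:
        for roi in self.rois:
            if roi.name == name:
                return roi
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.rois]


@dataclass(frozen=True)
class ControlPoint:
    gantry_deg: float
    cumulative_meterset: float
    mlc_bank_a_mm: np.ndarray  # leaf tips, retracting toward -X (mm at iso)
    mlc_bank_b_mm: np.ndarray
    jaw_x_mm: tuple[float, float]
    jaw_y_mm: tuple[float, float]
    collimator_deg: float


@dataclass
class PlanBeam:
    number: int
    name: str
    control_points: list[ControlPoint]
    gantry_rotation: str  # "CW" | "CC" | "NONE"
    leaf_boundaries_mm: np.ndarray

    def angular_span_deg(self) -> float:
        """Total gantry travel of the beam, unwrapped across 0/360."""
        angles = np.array([cp.gantry_deg for cp in self.control_points])
        unwrapped = np.unwrap(angles, period=360.0)
        return float(abs(unwrapped[-1] - unwrapped[0]))


@dataclass
class PlanInfo:
    isocenter_mm: tuple[float, float, float]
    beams: list[PlanBeam]
    nominal_energy_mv: float
    label: str = ""


# ---------------------------------------------------------------------------
# Patient <-> room bridge
# ---------------------------------------------------------------------------


def patient_to_room_cm(
    p_mm: Sequence[float], isocenter_mm: Sequence[float]
) -> tuple[float, float, float]:
    px, py, pz = (float(p_mm[i]) - float(isocenter_mm[i]) for i in range(3))
    return (px / 10.0, pz / 10.0, -py / 10.0)


def room_to_patient_mm(
    room_cm: Sequence[float], isocenter_mm: Sequence[float]
) -> tuple[float, float, float]:
    rx, ry, rz = (float(v) * 10.0 for v in room_cm)
    ix, iy, iz = (float(v) for v in isocenter_mm)
    return (ix + rx, iy - rz, iz + ry)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _ct_files(ct_series: str | Path | Sequence[str | Path]) -> list[Path]:
    if isinstance(ct_series, (str, Path)):
        p = Path(ct_series)
        if p.is_dir():
            return sorted(q for q in p.iterdir() if q.suffix.lower() == ".dcm")
        return [p]
    return [Path(p) for p in ct_series]


def read_ct_geometry(ct_series: str | Path | Sequence[str | Path]) -> CTGeometry:
    """Read the CT lattice from an image series (a directory or file list).

    File order is irrelevant; slices are sorted by position.  A single slice
    or a non-uniform slice spacing beyond 0.01 mm is an error.
    """
    files = _ct_files(ct_series)
    if not files:
        raise DicomIOError("no CT files found")
    datasets = [pydicom.dcmread(f) for f in files]
    frames = {ds.FrameOfReferenceUID for ds in datasets}
    if len(frames) != 1:
        raise DicomIOError(f"CT series mixes frames of reference: {sorted(frames)}")
    if len(datasets) < 2:
        raise DicomIOError("cannot establish slice spacing from a single CT slice")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    steps = np.diff(zs)
    if np.any(np.abs(steps - steps[0]) > _SLICE_SPACING_TOL_MM):
        raise DicomIOError("non-uniform slice spacing beyond 0.01 mm tolerance")
    first = datasets[0]
    orientation = tuple(float(v) for v in first.ImageOrientationPatient)
    if not np.allclose(orientation, (1, 0, 0, 0, 1, 0)):
        raise DicomIOError("only identity (head-first supine) orientation is supported")
    spacing = (
        float(first.PixelSpacing[0]),
        float(first.PixelSpacing[1]),
        float(steps[0]),
    )
    if min(spacing) <= 0:
        raise DicomIOError("voxel spacing must be strictly positive")
    origin = tuple(float(v) for v in first.ImagePositionPatient)
    dims = (int(first.Rows), int(first.Columns), len(datasets))
    return CTGeometry(origin_mm=origin, spacing_mm=spacing, dims=dims, orientation=orientation)


def read_structure_set(rtstruct: str | Path, ct: CTGeometry) -> StructureSet:
    """Read named ROIs with colors and closed planar contours (patient mm)."""
    ds = pydicom.dcmread(rtstruct)
    names = {
        int(item.ROINumber): str(item.ROIName)
        for item in ds.get("StructureSetROISequence", [])
    }
    rois: list[ROIContours] = []
    z0, dz, nz = ct.origin_mm[2], ct.spacing_mm[2], ct.dims[2]
    for item in ds.get("ROIContourSequence", []):
        number = int(item.ReferencedROINumber)
        color = tuple(int(c) for c in item.get("ROIDisplayColor", [255, 0, 0]))
        contours: list[np.ndarray] = []
        for c in item.get("ContourSequence", []):
            pts = np.asarray([float(v) for v in c.ContourData], dtype=float).reshape(-1, 3)
            if pts.shape[0] < 3:
                raise DicomIOError(f"ROI {names.get(number)}: contour with <3 vertices")
            if np.ptp(pts[:, 2]) > 1e-6:
                raise DicomIOError(f"ROI {names.get(number)}: non-axial contour rejected")
            k = (pts[0, 2] - z0) / dz
            if not (-0.5 <= k <= nz - 0.5) or abs(k - round(k)) > 0.5 + 1e-9:
                raise DicomIOError(
                    f"ROI {names.get(number)}: contour at z={pts[0, 2]:.2f} mm off the CT lattice"
                )
            contours.append(pts)
        if not contours:
            warnings.warn(f"ROI {names.get(number)!r} has no contours; kept empty")
        rois.append(ROIContours(name=names.get(number, f"ROI{number}"), color=color, contours=contours))
    return StructureSet(rois=rois)


def read_plan(rtplan: str | Path) -> PlanInfo:
    """Read isocenter, beams and per-control-point apertures from an RTPLAN."""
    ds = pydicom.dcmread(rtplan)
    beams: list[PlanBeam] = []
    isocenter = None
    energy = 6.0
    for beam in ds.get("BeamSequence", []):
        name = str(beam.get("BeamName", f"Beam{beam.BeamNumber}"))
        boundaries = None
        for bld in beam.get("BeamLimitingDeviceSequence", []):
            if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCY"):
                boundaries = np.asarray(
                    [float(v) for v in bld.LeafPositionBoundaries], dtype=float
                )
        cps: list[ControlPoint] = []
        gantry = None
        collimator = 0.0
        jaw_x = jaw_y = None
        mlc_a = mlc_b = None
        rotation = "NONE"
        for cp in beam.ControlPointSequence:
            if "GantryAngle" in cp:
                gantry = float(cp.GantryAngle)
            if "GantryRotationDirection" in cp and cp.GantryRotationDirection != "NONE":
                rotation = str(cp.GantryRotationDirection)
            if "BeamLimitingDeviceAngle" in cp:
                collimator = float(cp.BeamLimitingDeviceAngle)
            if "IsocenterPosition" in cp and isocenter is None:
                isocenter = tuple(float(v) for v in cp.IsocenterPosition)
            if "NominalBeamEnergy" in cp:
                energy = float(cp.NominalBeamEnergy)
            for bldp in cp.get("BeamLimitingDevicePositionSequence", []):
                kind = bldp.RTBeamLimitingDeviceType
                pos = [float(v) for v in bldp.LeafJawPositions]
                if kind in ("X", "ASYMX"):
                    jaw_x = (pos[0], pos[1])
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (pos[0], pos[1])
                elif kind in ("MLCX", "MLCY"):
                    half = len(pos) // 2
                    mlc_a = np.asarray(pos[:half], dtype=float)
                    mlc_b = np.asarray(pos[half:], dtype=float)
            if gantry is None or jaw_x is None or jaw_y is None or mlc_a is None:
                raise DicomIOError(f"beam {name!r}: missing gantry/MLC/jaw data at a control point")
            if len(mlc_a) != len(mlc_b):
                raise DicomIOError(f"beam {name!r}: unequal MLC bank lengths")
            cps.append(
                ControlPoint(
                    gantry_deg=gantry,
                    cumulative_meterset=float(cp.CumulativeMetersetWeight),
                    mlc_bank_a_mm=mlc_a.copy(),
                    mlc_bank_b_mm=mlc_b.copy(),
                    jaw_x_mm=jaw_x,
                    jaw_y_mm=jaw_y,
                    collimator_deg=collimator,
                )
            )
        if len(cps) < 2:
            raise DicomIOError(f"beam {name!r}: fewer than 2 control points")
        metersets = [cp.cumulative_meterset for cp in cps]
        if any(b < a for a, b in zip(metersets, metersets[1:])):
            raise DicomIOError(f"beam {name!r}: cumulative meterset not sorted")
        if boundaries is None:
            boundaries = np.arange(len(cps[0].mlc_bank_a_mm) + 1, dtype=float)
        beams.append(
            PlanBeam(
                number=int(beam.BeamNumber),
                name=name,
                control_points=cps,
                gantry_rotation=rotation,
                leaf_boundaries_mm=boundaries,
            )
        )
    if not beams:
        raise DicomIOError("plan contains no beams")
    if isocenter is None:
        raise DicomIOError("plan contains no isocenter position")
    return PlanInfo(
        isocenter_mm=isocenter,
        beams=beams,
        nominal_energy_mv=energy,
        label=str(ds.get("RTPlanLabel", "")),
    )


# ---------------------------------------------------------------------------
# Fixture writer
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SphereROI:
    name: str
    color: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class CylinderROI:
    """Axial cylinder (axis along patient z)."""

    name: str
    color: tuple[int, int, int]
    center_mm: tuple[float, float, float]
    radius_mm: float
    half_length_mm: float


@dataclass(frozen=True)
class ArcBeamSpec:
    """A full-circle arc with constant angular speed and a square open field."""

    speed_deg_s: float
    direction: str = "CW"  # CW = increasing gantry angle
    field_size_mm: float = 240.0
    collimator_deg: float = 0.0
    start_deg: float = 0.0
    span_deg: float = 360.0
    cp_step_deg: float = 10.0


@dataclass
class FixtureSpec:
    dims: tuple[int, int, int]  # rows, cols, slices
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    isocenter_mm: tuple[float, float, float]
    rois: list = field(default_factory=list)
    arcs: list = field(default_factory=lambda: [ArcBeamSpec(speed_deg_s=1.5)])
    energy_mv: float = 6.0
    label: str = "SYNTHETIC"
    seed: int = 0
    contour_vertices: int = 64

    @staticmethod
    def bb_validation(
        spacing_mm: tuple[float, float, float] = (0.5, 0.5, 1.0),
        speeds: Sequence[float] = (1.5, 4.8),
        field_size_mm: float = 240.0,
        seed: int = 0,
    ) -> "FixtureSpec":
        """End-to-end ball-bearing layout: an 8-mm sphere whose center sits
        10 cm lateral and 5 cm longitudinal from the plan isocenter (room
        coordinates (-10, -5, 0) cm), imaged by clockwise full arcs."""
        iso = (0.0, 0.0, 0.0)
        bb_patient = room_to_patient_mm((-10.0, -5.0, 0.0), iso)
        dims = (48, 48, 24)
        origin = (
            bb_patient[0] - (dims[1] - 1) / 2.0 * spacing_mm[1],
            bb_patient[1] - (dims[0] - 1) / 2.0 * spacing_mm[0],
            bb_patient[2] - (dims[2] - 1) / 2.0 * spacing_mm[2],
        )
        return FixtureSpec(
            dims=dims,
            spacing_mm=spacing_mm,
            origin_mm=origin,
            isocenter_mm=iso,
            rois=[SphereROI("BB", (255, 0, 0), bb_patient, 4.0)],
            arcs=[ArcBeamSpec(speed_deg_s=s, field_size_mm=field_size_mm) for s in speeds],
            seed=seed,
        )


def _uid(spec_seed: int, *parts: object) -> str:
    digest = hashlib.sha256(("|".join(map(str, (spec_seed,) + parts))).encode()).hexdigest()
    return "2.25." + str(int(digest[:30], 16))


def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta

def _base_dataset(sop_class: str, sop_instance: str, modality: str, spec: FixtureSpec) -> Dataset:
    ds = Dataset()
    ds.file_meta = _file_meta(sop_class, sop_instance)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_instance
    ds.Modality = modality
    ds.PatientName = "Synthetic^Phantom"
    ds.PatientID = f"SYN{spec.seed:04d}"
    ds.StudyInstanceUID = _uid(spec.seed, "study")
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.SeriesDate = ds.StudyDate
    return ds


def _roi_slice_polygons(roi, spec: FixtureSpec) -> list[np.ndarray]:
    """Analytic slice polygons for a sphere or cylinder on the CT lattice."""
    z0, dz, nz = spec.origin_mm[2], spec.spacing_mm[2], spec.dims[2]
    n = spec.contour_vertices
    angles = 2.0 * math.pi * np.arange(n) / n
    out = []
    for k in range(nz):
        z = z0 + k * dz
        if isinstance(roi, SphereROI):
            d = z - roi.center_mm[2]
            if abs(d) >= roi.radius_mm:
                continue
            r = math.sqrt(roi.radius_mm**2 - d * d)
        elif isinstance(roi, CylinderROI):
            if abs(z - roi.center_mm[2]) > roi.half_length_mm:
                continue
            r = roi.radius_mm
        else:
            raise DicomIOError(f"unsupported ROI shape: {roi!r}")
        if r < 1e-6:
            continue
        pts = np.column_stack(
            [
                roi.center_mm[0] + r * np.cos(angles),
                roi.center_mm[1] + r * np.sin(angles),
                np.full(n, z),
            ]
        )
        out.append(pts)
    return out


def _check_roi_in_grid(roi, spec: FixtureSpec) -> None:
    ox, oy, oz = spec.origin_mm
    sr, sc, ss = spec.spacing_mm
    lo = np.array([ox, oy, oz])
    hi = lo + np.array([(spec.dims[1] - 1) * sc, (spec.dims[0] - 1) * sr, (spec.dims[2] - 1) * ss])
    c = np.asarray(roi.center_mm, dtype=float)
    r = roi.radius_mm
    if np.any(c - r < lo - 1e-9) or np.any(c + r > hi + 1e-9):
        raise DicomIOError(f"ROI {roi.name!r} extends outside the CT grid")


def write_fixture_suite(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic CT series, RTSTRUCT and RTPLAN to ``out_dir``.

    Deterministic for a fixed spec (UIDs derived from the spec seed), so a
    write -> read -> write round trip is byte-identical.  Returns paths
    under keys ``ct_dir``, ``rtstruct`` and ``rtplan``.
    """
    out = Path(out_dir)
    ct_dir = out / "ct"
    ct_dir.mkdir(parents=True, exist_ok=True)
    for roi in spec.rois:
        _check_roi_in_grid(roi, spec)

    frame_uid = _uid(spec.seed, "frame")
    series_uid = _uid(spec.seed, "ct-series")
    rows, cols, slices = spec.dims[0], spec.dims[1], spec.dims[2]

    # CT voxel values: air background with radio-opaque ROI interiors, so the
    # series is also visually meaningful in a DICOM viewer.
    xs = spec.origin_mm[0] + np.arange(cols) * spec.spacing_mm[1]
    ys = spec.origin_mm[1] + np.arange(rows) * spec.spacing_mm[0]
    ct_sop_uids = []
    for k in range(slices):
        z = spec.origin_mm[2] + k * spec.spacing_mm[2]
        sop = _uid(spec.seed, "ct", k)
        ct_sop_uids.append(sop)
        ds = _base_dataset(_CT_SOP, sop, "CT", spec)
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [spec.origin_mm[0], spec.origin_mm[1], z]
        ds.PixelSpacing = [spec.spacing_mm[0], spec.spacing_mm[1]]
        ds.SliceThickness = spec.spacing_mm[2]
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = rows, cols
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleIntercept = -1024.0
        ds.RescaleSlope = 1.0
        img = np.zeros((rows, cols), dtype=np.uint16)
        for roi in spec.rois:
            cz = roi.center_mm[2]
            if isinstance(roi, SphereROI):
                d = z - cz
                if abs(d) >= roi.radius_mm:
                    continue
                r = math.sqrt(roi.radius_mm**2 - d * d)
            else:
                if abs(z - cz) > roi.half_length_mm:
                    continue
                r = roi.radius_mm
            dist2 = (xs[None, :] - roi.center_mm[0]) ** 2 + (ys[:, None] - roi.center_mm[1]) ** 2
            img[dist2 <= r * r] = 4000
        ds.PixelData = img.tobytes()
        ds.save_as(ct_dir / f"ct_{k:03d}.dcm", enforce_file_format=True)

    # RTSTRUCT
    struct_sop = _uid(spec.seed, "rtstruct")
    rs = _base_dataset(_RTSTRUCT_SOP, struct_sop, "RTSTRUCT", spec)
    rs.SeriesInstanceUID = _uid(spec.seed, "rtstruct-series")
    rs.StructureSetLabel = spec.label
    ref_frame = Dataset()
    ref_frame.FrameOfReferenceUID = frame_uid
    rs.ReferencedFrameOfReferenceSequence = [ref_frame]
    rs.StructureSetROISequence = []
    rs.ROIContourSequence = []
    rs.RTROIObservationsSequence = []
    for idx, roi in enumerate(spec.rois, start=1):
        sroi = Dataset()
        sroi.ROINumber = idx
        sroi.ROIName = roi.name
        sroi.ReferencedFrameOfReferenceUID = frame_uid
        sroi.ROIGenerationAlgorithm = "AUTOMATIC"
        rs.StructureSetROISequence.append(sroi)
        rc = Dataset()
        rc.ReferencedROINumber = idx
        rc.ROIDisplayColor = list(roi.color)
        rc.ContourSequence = []
        for pts in _roi_slice_polygons(roi, spec):
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = pts.shape[0]
            c.ContourData = [f"{v:.6f}" for v in pts.ravel()]
            rc.ContourSequence.append(c)
        rs.ROIContourSequence.append(rc)
        obs = Dataset()
        obs.ObservationNumber = idx
        obs.ReferencedROINumber = idx
        obs.RTROIInterpretedType = "MARKER"
        rs.RTROIObservationsSequence.append(obs)
    struct_path = out / "rtstruct.dcm"
    rs.save_as(struct_path, enforce_file_format=True)

    # RTPLAN
    plan_sop = _uid(spec.seed, "rtplan")
    rp = _base_dataset(_RTPLAN_SOP, plan_sop, "RTPLAN", spec)
    rp.SeriesInstanceUID = _uid(spec.seed, "rtplan-series")
    rp.FrameOfReferenceUID = frame_uid
    rp.RTPlanLabel = spec.label
    rp.RTPlanGeometry = "PATIENT"
    rp.BeamSequence = []
    n_leaves = 40
    leaf_bounds = np.linspace(-200.0, 200.0, n_leaves + 1)
    for bnum, arc in enumerate(spec.arcs, start=1):
        beam = Dataset()
        beam.BeamNumber = bnum
        beam.BeamName = f"Arc{bnum}"
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        beam.TreatmentDeliveryType = "TREATMENT"
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = n_leaves
        bld.LeafPositionBoundaries = [f"{v:.1f}" for v in leaf_bounds]
        beam.BeamLimitingDeviceSequence = [bld]
        half = arc.field_size_mm / 2.0
        n_cp = int(round(arc.span_deg / arc.cp_step_deg)) + 1
        sign = 1.0 if arc.direction == "CW" else -1.0
        beam.ControlPointSequence = []
        for i in range(n_cp):
            cp = Dataset()
            cp.ControlPointIndex = i
            cp.CumulativeMetersetWeight = f"{i / (n_cp - 1):.6f}"
            angle = (arc.start_deg + sign * i * arc.cp_step_deg) % 360.0
            cp.GantryAngle = f"{angle:.2f}"
            cp.GantryRotationDirection = arc.direction if i < n_cp - 1 else "NONE"
            if i == 0:
                cp.IsocenterPosition = [f"{v:.4f}" for v in spec.isocenter_mm]
                cp.NominalBeamEnergy = spec.energy_mv
                cp.BeamLimitingDeviceAngle = f"{arc.collimator_deg:.1f}"
                cp.DoseRateSet = 600.0
            jaws_x = Dataset()
            jaws_x.RTBeamLimitingDeviceType = "ASYMX"
            jaws_x.LeafJawPositions = [f"{-half:.1f}", f"{half:.1f}"]
            jaws_y = Dataset()
            jaws_y.RTBeamLimitingDeviceType = "ASYMY"
            jaws_y.LeafJawPositions = [f"{-half:.1f}", f"{half:.1f}"]
            mlc = Dataset()
            mlc.RTBeamLimitingDeviceType = "MLCX"
            open_a = np.where(
                (leaf_bounds[1:] > -half) & (leaf_bounds[:-1] < half), -half, 0.0
            )
            open_b = np.where(
                (leaf_bounds[1:] > -half) & (leaf_bounds[:-1] < half), half, 0.0
            )
            mlc.LeafJawPositions = [f"{v:.1f}" for v in np.concatenate([open_a, open_b])]
            cp.BeamLimitingDevicePositionSequence = [jaws_x, jaws_y, mlc]
            beam.ControlPointSequence.append(cp)
        beam.NumberOfControlPoints = n_cp
        # Arc timing metadata: meterset weight is proportional to elapsed
        # time, so constant angular speed = span / speed seconds total.
        beam.FinalCumulativeMetersetWeight = 1.0
        rp.BeamSequence.append(beam)
    fg = Dataset()
    fg.FractionGroupNumber = 1
    fg.NumberOfFractionsPlanned = 1
    fg.ReferencedBeamSequence = []
    for bnum, arc in enumerate(spec.arcs, start=1):
        rb = Dataset()
        rb.ReferencedBeamNumber = bnum
        rb.BeamMeterset = 1000.0
        fg.ReferencedBeamSequence.append(rb)
    rp.FractionGroupSequence = [fg]
    plan_path = out / "rtplan.dcm"
    rp.save_as(plan_path, enforce_file_format=True)

    return {"ct_dir": ct_dir, "rtstruct": struct_path, "rtplan": plan_path}
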