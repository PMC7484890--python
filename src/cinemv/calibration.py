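"""Panel-position calibration from ball-bearing arc acquisitions.

A radio-opaque ball bearing fixed at the isocenter casts a dark disk onto
the imager; gravity makes the panel sag by a gantry-angle-dependent
translation, so the disk wanders around the image center over an arc.  The
calibration detects the BB centroid on every frame and builds a correction
table holding, per gantry angle, the translation that brings the BB back to
the image center (native pixel coordinate (511.5, 511.5)) — the definition
of the beam axis used by the projection module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import LinacGeometry
from .image_pipeline import PanelCorrectionTable, PipelineError, ProcessedImage

__all__ = [
    "CalibrationError",
    "BBNotFoundError",
    "CalibrationRun",
    "detect_bb_centroid",
    "build_correction_table",
]


class CalibrationError(ValueError):
    pass


class BBNotFoundError(CalibrationError):
    pass


@dataclass
class CalibrationRun:
    """One 360-degree arc: rotation direction and (gantry angle, native-pixel
    BB centroid) samples."""

    direction: str  # "CW" | "CC"
    samples: list[tuple[float, tuple[float, float]]]


def detect_bb_centroid(
    image: ProcessedImage | np.ndarray,
    binned: bool | None = None,
    min_contrast: float = 0.1,
) -> tuple[float, float]:
    """Sub-pixel centroid of the BB shadow, in native pixel coordinates.

    The BB appears as a locally attenuated disk inside the bright open
    field.  Detection masks the field (above half maximum, eroded away from
    the penumbra), thresholds the inverted intensity halfway between the
    field median and the darkest blob pixel, keeps the largest connected
    blob and returns its attenuation-weighted centroid (x = column,
    y = row).  Raises :class:`BBNotFoundError` when no blob with at least
    ``min_contrast`` relative attenuation exists — never a silent (0, 0).
    """
    if isinstance(image, ProcessedImage):
        arr = np.asarray(image.pixels, dtype=np.float64)
        binned = True if binned is None else binned
    else:
        arr = np.asarray(image, dtype=np.float64)
        if binned is None:
            binned = arr.shape[0] <= 512
    vmax = arr.max()
    if vmax <= 0:
        raise BBNotFoundError("image is empty")
    field_mask = arr > 0.5 * vmax
    field_mask = ndimage.binary_erosion(field_mask, iterations=3, border_value=0)
    if not field_mask.any():
        raise BBNotFoundError("no open field found")
    med = float(np.median(arr[field_mask]))
    lo = float(arr[field_mask].min())
    if med <= 0 or (med - lo) < min_contrast * med:
        raise BBNotFoundError("no sufficiently attenuated blob inside the field")
    thr = 0.5 * (med - lo)
    inv = med - arr
    blob = (inv > thr) & field_mask
    labels, n = ndimage.label(blob)
    if n == 0:
        raise BBNotFoundError("no blob above the detection threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    best = int(np.argmax(sizes)) + 1
    mask = labels == best
    w = np.where(mask, np.clip(inv, 0.0, None), 0.0)
    total = w.sum()
    rows, cols = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]]
    y = float((w * rows).sum() / total)
    x = float((w * cols).sum() / total)
    if binned:
        x = 2.0 * x + 0.5
        y = 2.0 * y + 0.5
    return (x, y)


def build_correction_table(
    runs: Sequence[CalibrationRun],
    geom: LinacGeometry | None = None,
    grid_step_deg: float = 1.0,
    max_gap_deg: float = 5.0,
    joint: bool = True,
) -> PanelCorrectionTable | dict[str, PanelCorrectionTable]:
    """Average BB centroids over runs and turn them into a correction table.

    Offsets per angle are (511.5, 511.5) minus the average detected
    centroid, resampled onto a regular ``grid_step_deg`` grid with
    wrap-aware linear interpolation.  Runs in both rotation directions are
    averaged jointly by default; ``joint=False`` returns one table per
    direction (hysteresis inspection).
    """
    if not runs:
        raise CalibrationError("at least one calibration run is required")
    geom = geom or LinacGeometry()
    center = (geom.panel_matrix - 1) / 2.0  # 511.5

    if not joint:
        by_dir: dict[str, list[CalibrationRun]] = {}
        for run in runs:
            by_dir.setdefault(run.direction, []).append(run)
        return {
            d: build_correction_table(rs, geom, grid_step_deg, max_gap_deg, joint=True)
            for d, rs in by_dir.items()
        }

    grid = np.arange(0.0, 360.0, grid_step_deg)
    dx_all, dy_all = [], []
    for run in runs:
        if not run.samples:
            raise CalibrationError("calibration run holds no samples")
        ang = np.array([np.mod(a, 360.0) for a, _ in run.samples])
        cx = np.array([c[0] for _, c in run.samples])
        cy = np.array([c[1] for _, c in run.samples])
        order = np.argsort(ang)
        ang, cx, cy = ang[order], cx[order], cy[order]
        gaps = np.diff(np.concatenate([ang, [ang[0] + 360.0]]))
        bad = gaps > max_gap_deg
        if bad.any():
            where = ", ".join(f"{ang[i]:.1f}->{ang[i] + gaps[i]:.1f} deg" for i in np.nonzero(bad)[0])
            raise CalibrationError(f"angle gaps larger than {max_gap_deg} deg: {where}")
        # wrap-aware resampling to the regular grid
        ang_ext = np.concatenate([ang - 360.0, ang, ang + 360.0])
        cx_ext = np.tile(cx, 3)
        cy_ext = np.tile(cy, 3)
        dx_all.append(center - np.interp(grid, ang_ext, cx_ext))
        dy_all.append(center - np.interp(grid, ang_ext, cy_ext))
    dx = np.mean(dx_all, axis=0)
    dy = np.mean(dy_all, axis=0)
    try:
        return PanelCorrectionTable(grid, dx, dy)
    except PipelineError as exc:
        raise CalibrationError(str(exc)) from exc
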