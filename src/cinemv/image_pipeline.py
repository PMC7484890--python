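"""Portal-image preprocessing, contrast equalization and overlay rendering.

The raw 1024 x 1024, 16-bit frames pass through, in order: dark-frame
subtraction, flood-field gain correction, a panel-position translation that
re-centers the beam axis on the image center, a 3 x 3 median filter, and
2 x 2 mean binning down to the 512 x 512 working resolution.  Display
contrast then comes from a thresholded histogram equalization: pixels below
70% of the image maximum are zeroed and the rest are redistributed over
0..255 by their empirical CDF, after which precomputed ROI contours are
painted over the 8-bit image in their planning colors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .roi_projection import ContourOverlay

__all__ = [
    "PipelineError",
    "EPIDFrame",
    "GainCalibration",
    "PanelCorrectionTable",
    "ProcessedImage",
    "preprocess",
    "histogram_equalize",
    "render_overlay",
    "bin2x2",
    "median3x3",
]


class PipelineError(ValueError):
    pass


@dataclass
class EPIDFrame:
    """One raw frame: 1024 x 1024 uint16 pixels and the readout-completion
    timestamp (s)."""

    pixels: np.ndarray
    timestamp_s: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.shape != (1024, 1024):
            raise PipelineError(f"expected 1024x1024 frame, got {self.pixels.shape}")
        if self.pixels.dtype != np.uint16:
            raise PipelineError(f"expected uint16 frame, got {self.pixels.dtype}")


@dataclass
class GainCalibration:
    """Dark offset frame plus flood fields at several dose rates for one
    nominal energy."""

    dark: np.ndarray
    floods: list[tuple[float, np.ndarray]]  # (dose_rate, flood frame)
    energy_mv: float = 6.0

    @classmethod
    def ideal(cls, shape: tuple[int, int] = (1024, 1024), level: float = 30000.0) -> "GainCalibration":
        """Flat calibration (zero dark, uniform flood): an identity gain."""
        return cls(
            dark=np.zeros(shape, dtype=np.float64),
            floods=[(600.0, np.full(shape, level, dtype=np.float64))],
        )

    def flood_for(self, dose_rate: float | None) -> np.ndarray:
        if not self.floods:
            raise PipelineError("gain calibration holds no flood fields")
        if dose_rate is None:
            return self.floods[0][1]
        rates = np.array([r for r, _ in self.floods])
        return self.floods[int(np.argmin(np.abs(rates - dose_rate)))][1]


@dataclass
class PanelCorrectionTable:
    """Gantry-angle-indexed (AB, GT) panel offsets in native pixels.

    Offsets are the translation to apply to each image so the beam axis
    returns to the image center; periodic in angle, linearly interpolated.
    """

    angles_deg: np.ndarray
    dx_ab_px: np.ndarray
    dy_gt_px: np.ndarray

    MAX_OFFSET_PX = 16.0

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        self.dx_ab_px = np.asarray(self.dx_ab_px, dtype=float)
        self.dy_gt_px = np.asarray(self.dy_gt_px, dtype=float)
        if not (self.angles_deg.shape == self.dx_ab_px.shape == self.dy_gt_px.shape):
            raise PipelineError("correction table columns must have equal length")
        if np.any(np.abs(self.dx_ab_px) >= self.MAX_OFFSET_PX) or np.any(
            np.abs(self.dy_gt_px) >= self.MAX_OFFSET_PX
        ):
            raise PipelineError(f"panel offsets exceed sanity bound {self.MAX_OFFSET_PX} px")
        order = np.argsort(self.angles_deg)
        self.angles_deg = self.angles_deg[order]
        self.dx_ab_px = self.dx_ab_px[order]
        self.dy_gt_px = self.dy_gt_px[order]

    @classmethod
    def identity(cls) -> "PanelCorrectionTable":
        a = np.arange(0.0, 360.0, 1.0)
        return cls(a, np.zeros_like(a), np.zeros_like(a))

    def offset_at(self, theta_deg: float) -> tuple[float, float]:
        """Wrap-aware linear interpolation of the (AB, GT) offset."""
        t = float(np.mod(theta_deg, 360.0))
        a = np.concatenate([self.angles_deg, [self.angles_deg[0] + 360.0]])
        dx = np.concatenate([self.dx_ab_px, [self.dx_ab_px[0]]])
        dy = np.concatenate([self.dy_gt_px, [self.dy_gt_px[0]]])
        if t < a[0]:
            t += 360.0
        return (float(np.interp(t, a, dx)), float(np.interp(t, a, dy)))

    def save(self, path: str | Path) -> None:
        with Path(path).open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["angle_deg", "dx_px", "dy_px"])
            for a, dx, dy in zip(self.angles_deg, self.dx_ab_px, self.dy_gt_px):
                w.writerow([repr(float(a)), repr(float(dx)), repr(float(dy))])

    @classmethod
    def load(cls, path: str | Path) -> "PanelCorrectionTable":
        rows = list(csv.DictReader(Path(path).open()))
        return cls(
            np.array([float(r["angle_deg"]) for r in rows]),
            np.array([float(r["dx_px"]) for r in rows]),
            np.array([float(r["dy_px"]) for r in rows]),
        )


@dataclass
class ProcessedImage:
    """512 x 512 preprocessed intensities, plus the 8-bit display image once
    equalization has run."""

    pixels: np.ndarray
    timestamp_s: float = 0.0
    display: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def bin2x2(image: np.ndarray) -> np.ndarray:
    """2 x 2 mean binning (keeps the 16-bit intensity range)."""
    h, w = image.shape
    if h % 2 or w % 2:
        raise PipelineError("binning requires even dimensions")
    return image.reshape(h // 2, 2, w // 2, 2).mean(axis=(1, 3))


def median3x3(image: np.ndarray) -> np.ndarray:
    """3 x 3 median filter with edge-replicated borders."""
    return ndimage.median_filter(image, size=3, mode="nearest")


def _translate_int(image: np.ndarray, dx_col: int, dy_row: int) -> np.ndarray:
    """Integer-pixel translation with zero fill: a feature at (r, c) moves to
    (r + dy_row, c + dx_col)."""
    out = np.zeros_like(image)
    h, w = image.shape
    src_r = slice(max(0, -dy_row), min(h, h - dy_row))
    src_c = slice(max(0, -dx_col), min(w, w - dx_col))
    dst_r = slice(max(0, dy_row), min(h, h + dy_row))
    dst_c = slice(max(0, dx_col), min(w, w + dx_col))
    out[dst_r, dst_c] = image[src_r, src_c]
    return out


# ---------------------------------------------------------------------------
# Main pipeline
# ---------------------------------------------------------------------------


def preprocess(
    frame: EPIDFrame,
    cal: GainCalibration,
    table: PanelCorrectionTable,
    theta_deg: float,
    dose_rate: float | None = None,
) -> ProcessedImage:
    """Dark subtraction, gain correction, translation, median, binning.

    The gain step divides by (flood - dark) of the flood nearest in dose
    rate and rescales by its mean so the overall intensity scale is
    preserved; non-positive denominator pixels are replaced by their local
    median.  The translation is the correction-table offset at ``theta``,
    rounded to integer native pixels.
    """
    img = frame.pixels.astype(np.float64) - cal.dark
    np.clip(img, 0.0, None, out=img)

    flood = cal.flood_for(dose_rate)
    den = flood.astype(np.float64) - cal.dark
    bad = den <= 0
    if bad.any():
        den = np.where(bad, ndimage.median_filter(den, size=5, mode="nearest"), den)
        den = np.where(den <= 0, np.median(den[den > 0]), den)
    img = img / den * float(den.mean())

    dx, dy = table.offset_at(theta_deg)
    img = _translate_int(img, int(round(dx)), int(round(dy)))
    img = median3x3(img)
    return ProcessedImage(pixels=bin2x2(img), timestamp_s=frame.timestamp_s)


def histogram_equalize(pixels: np.ndarray, threshold_fraction: float = 0.70) -> np.ndarray:
    """Thresholded histogram equalization to an 8-bit display image.

    Pixels below ``threshold_fraction * max`` become 0; the retained pixels
    are mapped monotonically onto [0, 255] through their empirical CDF
    (min-shifted so the lowest retained level maps to 0 and a single
    retained level maps to 255).
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise PipelineError("threshold fraction must be in (0, 1)")
    img = np.asarray(pixels, dtype=np.float64)
    vmax = img.max()
    out = np.zeros(img.shape, dtype=np.uint8)
    if vmax <= 0:
        return out
    thr = threshold_fraction * vmax
    retained = img >= thr
    vals = img[retained]
    levels, inverse, counts = np.unique(vals, return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / vals.size
    cdf_min = cdf[0]
    if cdf_min >= 1.0:  # a single retained gray level
        out[retained] = 255
        return out
    mapped = np.rint(255.0 * (cdf[inverse] - cdf_min) / (1.0 - cdf_min)).astype(np.uint8)
    out[retained] = mapped
    return out


def render_overlay(
    display: np.ndarray,
    overlays: Sequence[ContourOverlay],
    visibility: dict[str, bool] | None = None,
) -> np.ndarray:
    """Paint contour pixels in their ROI colors over an 8-bit image.

    Returns an RGB uint8 image; ROIs switched off in ``visibility`` are not
    drawn and the grayscale background is untouched elsewhere.
    """
    if display.dtype != np.uint8:
        raise PipelineError("display image must be 8-bit")
    rgb = np.repeat(display[:, :, None], 3, axis=2).copy()
    h, w = display.shape
    for ov in overlays:
        if visibility is not None and not visibility.get(ov.roi_name, True):
            continue
        if ov.empty:
            continue
        cols = ov.boundary_pixels[:, 0]
        rows = ov.boundary_pixels[:, 1]
        if cols.max() >= w or rows.max() >= h or cols.min() < 0 or rows.min() < 0:
            raise PipelineError(
                f"overlay {ov.roi_name!r} resolution mismatch with {display.shape} display"
            )
        rgb[rows, cols] = np.array(ov.color, dtype=np.uint8)
    return rgb
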