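"""Offline replay, geometric-accuracy evaluation and visibility bookkeeping.

The accuracy analysis re-runs the full monitoring chain on an acquisition
(simulated or recorded): every frame is preprocessed, a readout-corrected
gantry angle is assigned per ROI, the precomputed contour for that angle is
looked up, and the signed difference between the contour centroid and the
detected BB centroid is reported in mm at isocenter scale.  In the AB
direction the polarity of the error is inverted for positive gantry angles
(theta in (0, 180) degrees), so that a negative error always means the
contour lags behind the object and a positive error always means it runs
ahead — which makes the mean of the errors a direct estimate of any
systematic gantry-angle or timing bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import BBNotFoundError, detect_bb_centroid
from .geometry import LinacGeometry, reduce_angle
from .image_pipeline import (
    EPIDFrame,
    GainCalibration,
    PanelCorrectionTable,
    histogram_equalize,
    preprocess,
    render_overlay,
)
from .roi_projection import ContourOverlay, ProjectionSet, lookup_index, lookup_overlay
from .stream_timing import MachineMessage, assign_roi_angle

__all__ = [
    "AccuracyReport",
    "VisibilityTrace",
    "evaluate_accuracy",
    "polarity_adjust",
    "visibility_trace",
    "count_visible_markers",
    "replay",
]


def polarity_adjust(err_ab_mm: float, theta_deg: float) -> float:
    """Invert the AB error sign for positive gantry angles.

    'Positive' means theta in (0, 180) degrees of the signed (-180, 180]
    convention, so after adjustment a negative error always indicates a
    contour lagging behind the object regardless of which side of the arc
    the gantry is on.
    """
    t = reduce_angle(theta_deg)
    return -err_ab_mm if 0.0 < t < 180.0 else err_ab_mm


@dataclass
class AccuracyReport:
    """Per-frame signed projection errors and their summary statistics."""

    table: pd.DataFrame  # columns: ts, theta_assigned, err_ab_mm, err_gt_mm, err_ab_adj_mm
    excluded_frames: int
    mu_ab_mm: float
    sigma_ab_mm: float
    mu_gt_mm: float
    sigma_gt_mm: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "mu_ab_mm": self.mu_ab_mm,
                "sigma_ab_mm": self.sigma_ab_mm,
                "mu_gt_mm": self.mu_gt_mm,
                "sigma_gt_mm": self.sigma_gt_mm,
                "n_frames": int(len(self.table)),
                "excluded_frames": self.excluded_frames,
            }
        )


def evaluate_accuracy(
    frames: Sequence[EPIDFrame],
    messages: Sequence[MachineMessage],
    pset: ProjectionSet,
    roi_name: str,
    cal: GainCalibration | None = None,
    table: PanelCorrectionTable | None = None,
    geom: LinacGeometry | None = None,
    bb_centroids_native: np.ndarray | None = None,
) -> AccuracyReport:
    """Retrospective projection-error analysis over an acquisition.

    Per frame: contour centroid (precomputed projection at the assigned
    angle) minus BB centroid (detected on the preprocessed image, or taken
    from ``bb_centroids_native`` ground truth when given), converted to mm
    at isocenter scale (one binned pixel = 0.5 mm); AB errors are
    polarity-adjusted by :func:`polarity_adjust`.  Frames without a
    detectable BB or with an empty overlay are excluded and counted.
    """
    geom = geom or LinacGeometry()
    cal = cal or GainCalibration.ideal()
    table = table if table is not None else PanelCorrectionTable.identity()
    center = (geom.panel_matrix - 1) / 2.0
    rows = []
    excluded = 0
    for i, frame in enumerate(frames):
        assignment = assign_roi_angle(frame.timestamp_s, messages, pset, roi_name, geom)
        overlay = lookup_overlay(pset, roi_name, assignment.theta_deg)
        if overlay.centroid is None or not assignment.refined:
            excluded += 1
            continue
        proc = preprocess(frame, cal, table, assignment.theta_deg)
        if bb_centroids_native is not None:
            bb_col, bb_row = bb_centroids_native[i]
        else:
            try:
                bb_col, bb_row = detect_bb_centroid(proc)
            except BBNotFoundError:
                excluded += 1
                continue
        cont_col = 2.0 * overlay.centroid[0] + 0.5  # binned -> native
        cont_row = 2.0 * overlay.centroid[1] + 0.5
        err_ab = (cont_col - bb_col) * geom.pixel_iso_mm
        err_gt = (cont_row - bb_row) * geom.pixel_iso_mm
        rows.append(
            {
                "ts": frame.timestamp_s,
                "theta_assigned": assignment.theta_deg,
                "err_ab_mm": err_ab,
                "err_gt_mm": err_gt,
                "err_ab_adj_mm": polarity_adjust(err_ab, assignment.theta_deg),
            }
        )
    df = pd.DataFrame(rows, columns=["ts", "theta_assigned", "err_ab_mm", "err_gt_mm", "err_ab_adj_mm"])
    if len(df):
        mu_ab = float(df["err_ab_adj_mm"].mean())
        sigma_ab = float(df["err_ab_adj_mm"].std(ddof=0))
        mu_gt = float(df["err_gt_mm"].mean())
        sigma_gt = float(df["err_gt_mm"].std(ddof=0))
    else:
        mu_ab = sigma_ab = mu_gt = sigma_gt = float("nan")
    return AccuracyReport(
        table=df,
        excluded_frames=excluded,
        mu_ab_mm=mu_ab,
        sigma_ab_mm=sigma_ab,
        mu_gt_mm=mu_gt,
        sigma_gt_mm=sigma_gt,
    )


# ---------------------------------------------------------------------------
# Marker visibility
# ---------------------------------------------------------------------------


def count_visible_markers(
    aperture_mask: np.ndarray,
    marker_centers: Sequence[tuple[float, float]],
    marker_radius_px: float,
    visible_fraction: float = 0.5,
) -> int:
    """Number of markers with at least ``visible_fraction`` of their
    projected disk inside the open aperture (binned pixel coordinates)."""
    h, w = aperture_mask.shape
    rows, cols = np.mgrid[0:h, 0:w]
    n = 0
    for cx, cy in marker_centers:
        disk = (cols - cx) ** 2 + (rows - cy) ** 2 <= marker_radius_px**2
        area = disk.sum()
        if area == 0:
            continue
        if (disk & aperture_mask).sum() / area >= visible_fraction:
            n += 1
    return n


@dataclass
class VisibilityTrace:
    """Per-frame visible-marker counts and continuous-visibility periods.

    The frequency is the inverse of the elapsed time between the first
    frames of two consecutive periods of continuous visibility; duration is
    the span of each period (inclusive of the final frame interval);
    ``fraction_visible`` is the fraction of frames in a visible period.
    """

    frame_ts: np.ndarray
    counts: np.ndarray
    min_markers: int = 1
    periods: list[tuple[int, int]] = field(default_factory=list)  # frame index ranges, inclusive

    @property
    def period_start_times(self) -> np.ndarray:
        return np.array([self.frame_ts[a] for a, _ in self.periods])

    @property
    def frequencies_hz(self) -> np.ndarray:
        starts = self.period_start_times
        if starts.size < 2:
            return np.empty(0)
        return 1.0 / np.diff(starts)

    @property
    def durations_s(self) -> np.ndarray:
        if not self.periods:
            return np.empty(0)
        dt = float(np.median(np.diff(self.frame_ts))) if self.frame_ts.size > 1 else 0.0
        return np.array([self.frame_ts[b] - self.frame_ts[a] + dt for a, b in self.periods])

    @property
    def fraction_visible(self) -> float:
        if self.counts.size == 0:
            return 0.0
        return float(np.count_nonzero(self.counts >= self.min_markers) / self.counts.size)


def visibility_trace(
    frame_ts: Sequence[float],
    counts: Sequence[int],
    min_markers: int = 1,
) -> VisibilityTrace:
    """Derive visibility periods from per-frame visible-marker counts."""
    ts = np.asarray(frame_ts, dtype=float)
    cnt = np.asarray(counts, dtype=int)
    if ts.shape != cnt.shape:
        raise ValueError("frame_ts and counts must have equal length")
    visible = cnt >= min_markers
    periods: list[tuple[int, int]] = []
    start = None
    for i, v in enumerate(visible):
        if v and start is None:
            start = i
        elif not v and start is not None:
            periods.append((start, i - 1))
            start = None
    if start is not None:
        periods.append((start, len(visible) - 1))
    return VisibilityTrace(frame_ts=ts, counts=cnt, min_markers=min_markers, periods=periods)


# ---------------------------------------------------------------------------
# Replay
# ---------------------------------------------------------------------------


def replay(
    frames: Sequence[EPIDFrame],
    messages: Sequence[MachineMessage],
    pset: ProjectionSet,
    cal: GainCalibration,
    table: PanelCorrectionTable,
    out_dir: str | Path,
    geom: LinacGeometry | None = None,
    roi_names: Sequence[str] | None = None,
    threshold_fraction: float = 0.70,
) -> list[dict]:
    """Offline replay of the treatment-time display computation.

    For every frame: preprocess, assign a readout-corrected angle per ROI,
    look up the precomputed overlay, equalize, render, and write one PNG.
    Returns the event log (also written as JSONL): per frame, the assigned
    angle and chosen overlay index per ROI.
    """
    from PIL import Image

    geom = geom or LinacGeometry()
    if cal is None or table is None:
        raise ValueError("replay requires gain calibration and a panel correction table")
    names = list(roi_names) if roi_names is not None else list(pset.overlays)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    with (out / "replay_log.jsonl").open("w") as fh:
        for i, frame in enumerate(frames):
            entry: dict = {"frame": i, "ts": frame.timestamp_s, "rois": {}}
            overlays: list[ContourOverlay] = []
            theta_for_proc = None
            for name in names:
                assignment = assign_roi_angle(frame.timestamp_s, messages, pset, name, geom)
                overlay = lookup_overlay(pset, name, assignment.theta_deg)
                overlays.append(overlay)
                idx = lookup_index(pset, assignment.theta_deg)
                entry["rois"][name] = {
                    "theta_assigned": assignment.theta_deg,
                    "overlay_index": idx,
                    "refined": assignment.refined,
                }
                theta_for_proc = assignment.theta_deg if theta_for_proc is None else theta_for_proc
            proc = preprocess(frame, cal, table, theta_for_proc or 0.0)
            display = histogram_equalize(proc.pixels, threshold_fraction)
            rgb = render_overlay(display, overlays)
            Image.fromarray(rgb).save(out / f"frame_{i:05d}.png")
            log.append(entry)
            fh.write(json.dumps(entry) + "\n")
    return log
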