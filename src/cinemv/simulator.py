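"""Synthetic linac + EPID acquisition generator.

Stands in for the accelerator, message stream and flat panel: renders
rolling-shutter frames of a ball-bearing phantom along a gantry trajectory,
emits a ~4 Hz machine-message stream with configurable receive-timestamp
jitter, injects panel sag, gain structure and detector noise, and records
complete ground truth for every frame.  The column-by-column readout is
implemented here from scratch (each native column is drawn with the gantry
geometry at its own readout time), independently of the timing-correction
code it is used to validate, so the end-to-end accuracy test exercises two
separate implementations of the same physics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
import numpy as np

from .geometry import LinacGeometry
from .image_pipeline import EPIDFrame
from .stream_timing import MachineMessage, write_messages

__all__ = [
    "SimulationError",
    "TrajectorySegment",
    "SimConfig",
    "GroundTruth",
    "bb_validation_config",
    "simulate_messages",
    "render_frame",
    "simulate_arc",
    "SimResult",
]

_BB_ATTENUATION = 0.40  # fractional intensity dip of the BB shadow
_FIELD_LEVEL = 30000.0
_BACKGROUND_LEVEL = 500.0


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class TrajectorySegment:
    """Constant gantry speed for a duration; positive speed = clockwise
    (increasing gantry angle)."""

    speed_deg_s: float
    duration_s: float


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic acquisition.

    Defaults mirror the end-to-end validation layout: an 8-mm BB offset
    10 cm laterally and 5 cm longitudinally from the isocenter, a 24 cm x
    24 cm open field, a clockwise full arc, messages at 4 Hz with +/-50 ms
    uniform receive jitter.
    """

    bb_center_cm: tuple[float, float, float] = (-10.0, -5.0, 0.0)
    bb_diameter_mm: float = 8.0
    start_deg: float = 0.0
    segments: tuple[TrajectorySegment, ...] = (TrajectorySegment(1.5, 240.0),)
    message_rate_hz: float = 4.0
    message_jitter_s: float = 0.05
    noise_sigma: float = 100.0
    sag_amp_ab_px: float = 0.0
    sag_phase_ab_deg: float = 0.0
    sag_amp_gt_px: float = 0.0
    sag_phase_gt_deg: float = 0.0
    gain_field: np.ndarray | None = None
    field_size_cm: float = 24.0
    seed: int = 0
    max_speed_deg_s: float = 4.8  # clinical VMAT envelope

    def __post_init__(self) -> None:
        for seg in self.segments:
            if abs(seg.speed_deg_s) > self.max_speed_deg_s + 1e-9:
                raise SimulationError(
                    f"gantry speed {seg.speed_deg_s} deg/s exceeds the "
                    f"{self.max_speed_deg_s} deg/s envelope"
                )
            if seg.duration_s <= 0:
                raise SimulationError("segment duration must be positive")
        if self.message_jitter_s < 0 or self.message_rate_hz <= 0:
            raise SimulationError("invalid message rate / jitter")

    @property
    def duration_s(self) -> float:
        return sum(seg.duration_s for seg in self.segments)

    def theta_at(self, t: float | np.ndarray) -> np.ndarray:
        """True gantry angle (deg, reduced to [0, 360)) at simulation time
        ``t``; clamped to the trajectory endpoints outside [0, duration]."""
        t = np.asarray(t, dtype=float)
        theta = np.full(t.shape, self.start_deg, dtype=float)
        t_clamped = np.clip(t, 0.0, self.duration_s)
        elapsed = np.zeros_like(t_clamped)
        for seg in self.segments:
            dt = np.clip(t_clamped - elapsed, 0.0, seg.duration_s)
            theta += seg.speed_deg_s * dt
            elapsed += seg.duration_s
        return np.mod(theta, 360.0)

    def sag_at(self, theta_deg: float) -> tuple[float, float]:
        """Panel-sag image shift (AB, GT) in native pixels at one angle."""
        dx = self.sag_amp_ab_px * math.sin(math.radians(theta_deg + self.sag_phase_ab_deg))
        dy = self.sag_amp_gt_px * math.sin(math.radians(theta_deg + self.sag_phase_gt_deg))
        return dx, dy


def bb_validation_config(
    speed_deg_s: float = 1.5,
    seed: int = 0,
    jitter_s: float = 0.05,
    noise_sigma: float = 100.0,
    **overrides,
) -> SimConfig:
    """End-to-end validation preset: clockwise 360-degree arc at the given
    speed, BB at room (-10, -5, 0) cm, 24 cm x 24 cm field."""
    cfg = SimConfig(
        segments=(TrajectorySegment(abs(speed_deg_s), 360.0 / abs(speed_deg_s)),),
        message_jitter_s=jitter_s,
        noise_sigma=noise_sigma,
        seed=seed,
    )
    return replace(cfg, **overrides) if overrides else cfg


@dataclass
class GroundTruth:
    """Per-frame and per-message truth exported by the simulator."""

    frame_ts: np.ndarray  # (F,)
    theta_at_ts: np.ndarray  # (F,) true angle at each frame timestamp
    bb_centroid_native: np.ndarray  # (F, 2) (col, row) as rendered
    theta_at_centroid: np.ndarray  # (F,) true angle at the centroid column readout
    message_true_ts: np.ndarray
    message_reported_ts: np.ndarray

    def save(self, path: str | Path) -> None:
        doc = {
            k: getattr(self, k).tolist()
            for k in (
                "frame_ts",
                "theta_at_ts",
                "bb_centroid_native",
                "theta_at_centroid",
                "message_true_ts",
                "message_reported_ts",
            )
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v, dtype=float) for k, v in doc.items()})


# ---------------------------------------------------------------------------
# Messages
# ---------------------------------------------------------------------------


def simulate_messages(cfg: SimConfig, pad_s: float = 1.0) -> list[MachineMessage]:
    """Machine-message stream over the trajectory (plus ``pad_s`` margin).

    Angles are sampled from the true trajectory at the true send times; the
    reported timestamps carry uniform receive jitter.  Jitter large enough
    to break timestamp monotonicity at the message rate is rejected.
    """
    interval = 1.0 / cfg.message_rate_hz
    if 2.0 * cfg.message_jitter_s >= interval:
        raise SimulationError("jitter half-width must be below half the message interval")
    rng = np.random.default_rng([cfg.seed, 1])
    true_ts = np.arange(-pad_s, cfg.duration_s + pad_s + interval / 2.0, interval)
    jitter = rng.uniform(-cfg.message_jitter_s, cfg.message_jitter_s, size=true_ts.size)
    reported = true_ts + jitter
    angles = cfg.theta_at(true_ts)
    msgs = [
        MachineMessage(timestamp_s=float(r), gantry_deg=float(a))
        for r, a in zip(reported, angles)
    ]
    return msgs


# ---------------------------------------------------------------------------
# Frame rendering
# ---------------------------------------------------------------------------


def _column_times(ts: float, geom: LinacGeometry) -> np.ndarray:
    """Per-native-column readout times: both panel halves read outside-in."""
    n = geom.panel_matrix
    c = np.arange(n)
    alpha = np.where(c <= n // 2 - 1, c, (n - 1) - c)
    return ts - geom.integration_time_s + alpha * geom.integration_time_s / (n // 2 - 1)


def _bb_image_position(
    cfg: SimConfig, theta_deg: np.ndarray, geom: LinacGeometry
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Native (col, row) of the BB center and its projected radius (px) for
    an array of gantry angles (closed-form central projection)."""
    x, y, z = cfg.bb_center_cm
    th = np.radians(theta_deg)
    sin_t, cos_t = np.sin(th), np.cos(th)
    den = geom.sad_cm - (x * sin_t + z * cos_t)
    scale = geom.sad_cm / den
    u_mm = 10.0 * scale * (x * cos_t - z * sin_t)
    v_mm = 10.0 * scale * y
    center = (geom.panel_matrix - 1) / 2.0
    col = center + u_mm / geom.pixel_iso_mm
    row = center + v_mm / geom.pixel_iso_mm
    radius_px = (cfg.bb_diameter_mm / 2.0) * scale / geom.pixel_iso_mm
    return col, row, radius_px


def render_frame(
    cfg: SimConfig,
    ts: float,
    geom: LinacGeometry | None = None,
    frame_index: int = 0,
) -> EPIDFrame:
    """Render one rolling-shutter frame stamped ``ts`` (readout completion).

    Every native column is drawn with the gantry geometry at that column's
    own readout time on the true (jitter-free) trajectory; panel sag is a
    whole-frame translation evaluated at theta(TS); the gain field and
    Gaussian noise apply last, clipped to 16 bits.  Deterministic for fixed
    (seed, frame_index).
    """
    geom = geom or LinacGeometry()
    n = geom.panel_matrix
    t_cols = _column_times(ts, geom)
    theta_cols = cfg.theta_at(t_cols)
    theta_ts = float(cfg.theta_at(np.array(ts)))
    sag_dx, sag_dy = cfg.sag_at(theta_ts)

    col_bb, row_bb, radius = _bb_image_position(cfg, theta_cols, geom)
    col_bb = col_bb + sag_dx
    row_bb = row_bb + sag_dy

    center = (n - 1) / 2.0
    half_px = cfg.field_size_cm * 10.0 / 2.0 / geom.pixel_iso_mm
    cols = np.arange(n, dtype=float)
    rows = np.arange(n, dtype=float)
    fa_c = np.clip(half_px + 0.5 - np.abs(cols - (center + sag_dx)), 0.0, 1.0)
    fa_r = np.clip(half_px + 0.5 - np.abs(rows - (center + sag_dy)), 0.0, 1.0)
    field_alpha = fa_r[:, None] * fa_c[None, :]

    img = _BACKGROUND_LEVEL + (_FIELD_LEVEL - _BACKGROUND_LEVEL) * field_alpha
    # The disk only spans a small window of rows/columns; render it locally.
    rmax = float(radius.max())
    c_lo = max(0, int(np.floor(col_bb.min() - rmax - 2)))
    c_hi = min(n - 1, int(np.ceil(col_bb.max() + rmax + 2)))
    r_lo = max(0, int(np.floor(row_bb.min() - rmax - 2)))
    r_hi = min(n - 1, int(np.ceil(row_bb.max() + rmax + 2)))
    if c_lo <= c_hi and r_lo <= r_hi:
        sub_rows = rows[r_lo : r_hi + 1]
        sub_cols = slice(c_lo, c_hi + 1)
        dist = np.sqrt(
            (sub_rows[:, None] - row_bb[None, sub_cols]) ** 2
            + (cols[None, sub_cols] - col_bb[None, sub_cols]) ** 2
        )
        disk_alpha = np.clip(radius[None, sub_cols] + 0.5 - dist, 0.0, 1.0)
        img[r_lo : r_hi + 1, sub_cols] *= 1.0 - _BB_ATTENUATION * disk_alpha
    if cfg.gain_field is not None:
        img *= cfg.gain_field
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng([cfg.seed, 2, frame_index])
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return EPIDFrame(pixels=np.clip(img, 0, 65535).astype(np.uint16), timestamp_s=ts)


def _true_bb_centroid(cfg: SimConfig, ts: float, geom: LinacGeometry) -> tuple[float, float, float]:
    """Fixed point of 'centroid column = BB column at that column's readout
    time': the rendered BB center and the true angle at its readout time."""
    theta = float(cfg.theta_at(np.array(ts)))
    sag_dx, sag_dy = cfg.sag_at(theta)
    col = float(_bb_image_position(cfg, np.array([theta]), geom)[0][0]) + sag_dx
    t_col = ts
    for _ in range(4):
        c_idx = int(np.clip(round(col), 0, geom.panel_matrix - 1))
        t_col = float(_column_times(ts, geom)[c_idx])
        th = cfg.theta_at(np.array([t_col]))
        c, r, _ = _bb_image_position(cfg, th, geom)
        col = float(c[0]) + sag_dx
        row = float(r[0]) + sag_dy
    return col, row, float(cfg.theta_at(np.array(t_col)))


@dataclass
class SimResult:
    config: SimConfig
    frames: list[EPIDFrame]
    messages: list[MachineMessage]
    truth: GroundTruth


def simulate_arc(
    cfg: SimConfig,
    geom: LinacGeometry | None = None,
    out_dir: str | Path | None = None,
) -> SimResult:
    """Simulate a full acquisition: frames at the panel frame rate spanning
    the trajectory, the jittered message stream, and complete ground truth.

    With ``out_dir`` set, frames are written as 16-bit TIFFs with a JSONL
    timestamp sidecar, messages as CSV, and ground truth as JSON.
    """
    geom = geom or LinacGeometry()
    t_int = geom.integration_time_s
    frame_ts = np.arange(t_int, cfg.duration_s + 1e-9, t_int)
    messages = simulate_messages(cfg)
    frames = [
        render_frame(cfg, float(ts), geom, frame_index=i) for i, ts in enumerate(frame_ts)
    ]
    cent = np.empty((frame_ts.size, 2))
    th_cent = np.empty(frame_ts.size)
    for i, ts in enumerate(frame_ts):
        col, row, th = _true_bb_centroid(cfg, float(ts), geom)
        cent[i] = (col, row)
        th_cent[i] = th
    interval = 1.0 / cfg.message_rate_hz
    true_ts = np.arange(-1.0, cfg.duration_s + 1.0 + interval / 2.0, interval)
    truth = GroundTruth(
        frame_ts=frame_ts,
        theta_at_ts=cfg.theta_at(frame_ts),
        bb_centroid_native=cent,
        theta_at_centroid=th_cent,
        message_true_ts=true_ts,
        message_reported_ts=np.array([m.timestamp_s for m in messages]),
    )
    result = SimResult(config=cfg, frames=frames, messages=messages, truth=truth)
    if out_dir is not None:
        _write_artifacts(result, Path(out_dir))
    return result


def _write_artifacts(result: SimResult, out: Path) -> None:
    import tifffile

    frames_dir = out / "frames"
    frames_dir.mkdir(parents=True, exist_ok=True)
    with (out / "frames.jsonl").open("w") as sidecar:
        for i, frame in enumerate(result.frames):
            name = f"frame_{i:05d}.tif"
            tifffile.imwrite(frames_dir / name, frame.pixels)
            sidecar.write(json.dumps({"file": name, "timestamp_s": frame.timestamp_s}) + "\n")
    write_messages(result.messages, out / "messages.csv")
    result.truth.save(out / "ground_truth.json")
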