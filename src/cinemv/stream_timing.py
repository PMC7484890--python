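"""Frame timing and gantry-angle assignment.

The flat panel reads its two lateral halves synchronously, column by
column, from the outside in: on the A side the readout starts at column
c = 0 and ends at c = 511 after one integration time (0.433 s); on the B
side it starts at c = 1023 and ends at c = 512.  With TS the frame
timestamp (readout completion), the readout time of column c is

    t(c) = TS - T + alpha(c) * T / 511,   T = 0.433 s,
    alpha(c) = c            for c in [0, 511]
    alpha(c) = 1023 - c     for c in [512, 1023]

Because the machine reports its gantry angle only at ~4 Hz, the angle for a
frame is obtained by linear interpolation of the message stream on the
unwrapped angle.  For an off-center ROI the relevant time is not TS but the
readout time of the column under the ROI: the assignment first interpolates
at TS, reads the precomputed projection centroid for that angle, converts
its column through the readout model, and re-interpolates at that time.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import LinacGeometry, reduce_angle
from .roi_projection import ProjectionSet, lookup_overlay

__all__ = [
    "TimingError",
    "MachineMessage",
    "AngleAssignment",
    "column_readout_time",
    "interpolate_angle",
    "assign_roi_angle",
    "write_messages",
    "read_messages",
]


class TimingError(ValueError):
    pass


@dataclass(frozen=True)
class MachineMessage:
    """One machine-state sample: receive timestamp (s, monotone clock),
    gantry angle (deg), linac state, dose rate (a.u.), nominal energy (MV)."""

    timestamp_s: float
    gantry_deg: float
    state: str = "BeamOn"
    dose_rate: float = 600.0
    energy_mv: float = 6.0


@dataclass(frozen=True)
class AngleAssignment:
    theta_deg: float
    native_column: int | None
    refined: bool  # False when the overlay was empty and theta(TS) was used


def column_readout_time(
    ts: float, c: int, geom: LinacGeometry | None = None
) -> float:
    """Readout time of native column ``c`` for a frame stamped ``ts``."""
    geom = geom or LinacGeometry()
    n = geom.panel_matrix
    if not (0 <= c <= n - 1):
        raise TimingError(f"column {c} out of range [0, {n - 1}]")
    half = n // 2 - 1  # 511
    alpha = c if c <= half else (n - 1) - c
    t_int = geom.integration_time_s
    return ts - t_int + alpha * t_int / half


def _message_arrays(messages: Sequence[MachineMessage]) -> tuple[np.ndarray, np.ndarray]:
    if not messages:
        raise TimingError("empty message stream")
    ts = np.array([m.timestamp_s for m in messages], dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise TimingError("message timestamps must be strictly increasing")
    theta = np.array([m.gantry_deg for m in messages], dtype=float)
    return ts, theta


def interpolate_angle(messages: Sequence[MachineMessage], t: float) -> float:
    """Gantry angle at time ``t``, linearly interpolated on the unwrapped
    angle (continuous across 0/360) and reduced to [0, 360).

    Times up to one typical message interval outside the stream coverage are
    clamped to the nearest endpoint; farther times are an error.
    """
    ts, theta = _message_arrays(messages)
    if len(ts) == 1:
        interval = math.inf
    else:
        interval = float(np.median(np.diff(ts)))
    if t < ts[0] - interval or t > ts[-1] + interval:
        raise TimingError(
            f"time {t:.3f} s outside message coverage [{ts[0]:.3f}, {ts[-1]:.3f}] s"
        )
    unwrapped = np.unwrap(theta, period=360.0)
    return reduce_angle(float(np.interp(t, ts, unwrapped)))


def assign_roi_angle(
    ts: float,
    messages: Sequence[MachineMessage],
    pset: ProjectionSet,
    roi_name: str,
    geom: LinacGeometry | None = None,
    max_iterations: int = 1,
    tol_deg: float = 0.05,
) -> AngleAssignment:
    """Assign a readout-time-corrected gantry angle to one frame and ROI.

    One refinement step by default; ``max_iterations > 1`` enables the
    fixed-point mode, stopping early once the angle moves by < ``tol_deg``.
    Frames whose overlay is empty at the first-pass angle fall back to the
    plain interpolation at TS (``refined=False``).
    """
    geom = geom or LinacGeometry()
    theta = interpolate_angle(messages, ts)
    column: int | None = None
    for _ in range(max_iterations):
        overlay = lookup_overlay(pset, roi_name, theta)
        if overlay.centroid is None:
            if column is None:
                return AngleAssignment(theta_deg=theta, native_column=None, refined=False)
            break
        col_binned = overlay.centroid[0]
        column = int(np.clip(round(2.0 * col_binned), 0, geom.panel_matrix - 1))
        t_col = column_readout_time(ts, column, geom)
        new_theta = interpolate_angle(messages, t_col)
        done = abs((new_theta - theta + 180.0) % 360.0 - 180.0) < tol_deg
        theta = new_theta
        if done:
            break
    return AngleAssignment(theta_deg=theta, native_column=column, refined=True)


# ---------------------------------------------------------------------------
# Stream log format (CSV / JSONL)
# ---------------------------------------------------------------------------

_FIELDS = ["timestamp_s", "gantry_deg", "state", "dose_rate", "energy_mv"]


def write_messages(messages: Sequence[MachineMessage], path: str | Path) -> None:
    """Write a message log; CSV or JSONL by file extension."""
    path = Path(path)
    if path.suffix == ".jsonl":
        with path.open("w") as fh:
            for m in messages:
                fh.write(json.dumps({f: getattr(m, f) for f in _FIELDS}) + "\n")
    else:
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(_FIELDS)
            for m in messages:
                w.writerow([repr(m.timestamp_s), repr(m.gantry_deg), m.state, m.dose_rate, m.energy_mv])


def read_messages(path: str | Path) -> list[MachineMessage]:
    path = Path(path)
    out: list[MachineMessage] = []
    if path.suffix == ".jsonl":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(MachineMessage(**{f: d[f] for f in _FIELDS if f in d}))
    else:
        with path.open() as fh:
            for row in csv.DictReader(fh):
                out.append(
                    MachineMessage(
                        timestamp_s=float(row["timestamp_s"]),
                        gantry_deg=float(row["gantry_deg"]),
                        state=row["state"],
                        dose_rate=float(row["dose_rate"]),
                        energy_mv=float(row["energy_mv"]),
                    )
                )
    return out
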