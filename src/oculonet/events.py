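"""Saccade and fixation detection from gaze-sample streams.

A composite detector in the classical I-VT / I-DT family: contiguous runs
of angular speed at or above a velocity threshold become saccades; the
remaining spans are greedily grouped into fixations whose positional
dispersion (range in x plus range in y, computed on smoothed positions)
stays below a dispersion threshold.  Samples flagged invalid split events;
nothing is interpolated by default.

Coordinates are degrees of visual angle relative to screen centre
(x rightward, y upward); helpers convert between pixels and degrees for a
known screen geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DetectionError

__all__ = [
    "GazeRecording",
    "OculomotorEvent",
    "DetectionParams",
    "ScreenGeometry",
    "compute_velocity",
    "detect_events",
    "px_to_deg",
    "deg_to_px",
    "events_to_dataframe",
]


@dataclass
class GazeRecording:
    """Time-ordered gaze samples for one trial.

    ``t_ms`` must be strictly increasing with spacing within 10% of the
    nominal sample period 1000 / ``sampling_rate``.
    """

    subject_id: str
    trial_id: str
    sampling_rate: float
    t_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t_ms.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.t_ms.size
        if not (self.x_deg.size == self.y_deg.size == self.valid.size == n):
            raise ValueError("t_ms, x_deg, y_deg, valid must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if n >= 2:
            dt = np.diff(self.t_ms)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            nominal = 1000.0 / self.sampling_rate
            if np.any(np.abs(dt - nominal) > 0.1 * nominal):
                raise ValueError(
                    "sample spacing deviates more than 10% from the nominal period"
                )

    def __len__(self) -> int:
        return int(self.t_ms.size)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sampling_rate: float) -> "GazeRecording":
        """Build from the gaze CSV dialect
        (subject_id, trial_id, t_ms, x_deg, y_deg, valid)."""
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            trial_id=str(df["trial_id"].iloc[0]),
            sampling_rate=sampling_rate,
            t_ms=df["t_ms"].to_numpy(),
            x_deg=df["x_deg"].to_numpy(),
            y_deg=df["y_deg"].to_numpy(),
            valid=df["valid"].to_numpy().astype(bool),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "trial_id": self.trial_id,
                "t_ms": self.t_ms,
                "x_deg": self.x_deg,
                "y_deg": self.y_deg,
                "valid": self.valid.astype(int),
            }
        )


@dataclass(frozen=True)
class OculomotorEvent:
    """A detected saccade or fixation."""

    kind: str  # "saccade" | "fixation"
    onset_ms: float
    offset_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    amplitude_deg: float
    peak_velocity_dps: float

    def __post_init__(self) -> None:
        if self.kind not in ("saccade", "fixation"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.offset_ms <= self.onset_ms:
            raise ValueError("offset must exceed onset")
        if self.amplitude_deg < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms

    def direction(self) -> tuple[float, float]:
        """Unit displacement vector (zero vector for no net displacement)."""
        dx = self.end_xy[0] - self.start_xy[0]
        dy = self.end_xy[1] - self.start_xy[1]
        norm = math.hypot(dx, dy)
        if norm == 0:
            return (0.0, 0.0)
        return (dx / norm, dy / norm)


@dataclass(frozen=True)
class DetectionParams:
    """Detector thresholds.

    Defaults are standard I-VT / I-DT operating points for 250 Hz data:
    30 deg/s velocity threshold, 1.0 degree dispersion ceiling, 50 ms
    minimum fixation, 12 ms minimum saccade, 5-sample position smoothing.
    """

    velocity_threshold_dps: float = 30.0
    dispersion_threshold_deg: float = 1.0
    min_fixation_ms: float = 50.0
    min_saccade_ms: float = 12.0
    smoothing_window_samples: int = 5
    interpolate_max_gap: int = 0  # linear interpolation for gaps <= this (samples)

    def __post_init__(self) -> None:
        for name in (
            "velocity_threshold_dps",
            "dispersion_threshold_deg",
            "min_fixation_ms",
            "min_saccade_ms",
            "smoothing_window_samples",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _nan_moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average ignoring NaNs; shrinks near edges/gaps."""
    if window <= 1:
        return x.copy()
    mask = np.isfinite(x)
    vals = np.where(mask, x, 0.0)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(mask.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _smoothed_positions(
    rec: GazeRecording, window: int, interpolate_max_gap: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Smoothed x, y and the effective validity mask."""
    valid = rec.valid.copy()
    x = np.where(valid, rec.x_deg, np.nan)
    y = np.where(valid, rec.y_deg, np.nan)
    if interpolate_max_gap > 0:
        x, y, valid = _fill_short_gaps(rec.t_ms, x, y, valid, interpolate_max_gap)
    xs = _nan_moving_average(x, window)
    ys = _nan_moving_average(y, window)
    return xs, ys, valid


def _fill_short_gaps(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, valid: np.ndarray, max_gap: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    valid = valid.copy()
    i = 0
    n = valid.size
    while i < n:
        if valid[i]:
            i += 1
            continue
        j = i
        while j < n and not valid[j]:
            j += 1
        if 0 < i and j < n and (j - i) <= max_gap:
            for arr in (x, y):
                arr[i:j] = np.interp(t[i:j], [t[i - 1], t[j]], [arr[i - 1], arr[j]])
            valid[i:j] = True
        i = j
    return x, y, valid


def compute_velocity(
    rec: GazeRecording, smoothing_window: int = 5
) -> np.ndarray:
    """Per-sample angular speed (deg/s) from smoothed positions.

    Interior samples use central differences; the first and last valid
    samples of each contiguous valid segment use one-sided differences.
    Samples that are invalid (or whose required neighbours are) get NaN.
    """
    if int(np.sum(rec.valid)) < 2:
        raise DetectionError("need at least 2 valid samples to compute velocity")
    xs, ys, valid = _smoothed_positions(rec, smoothing_window)
    t = rec.t_ms
    n = len(rec)
    speed = np.full(n, np.nan)

    if valid.all() and n >= 2:
        dt_s = np.empty(n)
        dt_s[1:-1] = (t[2:] - t[:-2]) / 1000.0
        dt_s[0] = (t[1] - t[0]) / 1000.0
        dt_s[-1] = (t[-1] - t[-2]) / 1000.0
        dx = np.empty(n)
        dy = np.empty(n)
        dx[1:-1] = xs[2:] - xs[:-2]
        dy[1:-1] = ys[2:] - ys[:-2]
        dx[0], dy[0] = xs[1] - xs[0], ys[1] - ys[0]
        dx[-1], dy[-1] = xs[-1] - xs[-2], ys[-1] - ys[-2]
        return np.hypot(dx, dy) / dt_s

    def _speed(i: int, j: int) -> float:
        dt_s = (t[j] - t[i]) / 1000.0
        return math.hypot(xs[j] - xs[i], ys[j] - ys[i]) / dt_s

    for i in range(n):
        if not valid[i]:
            continue
        left = i - 1 if i > 0 and valid[i - 1] else None
        right = i + 1 if i < n - 1 and valid[i + 1] else None
        if left is not None and right is not None:
            speed[i] = _speed(left, right)
        elif right is not None:
            speed[i] = _speed(i, right)
        elif left is not None:
            speed[i] = _speed(left, i)
    return speed


def _dispersion(xs: np.ndarray, ys: np.ndarray, lo: int, hi: int) -> float:
    """range_x + range_y over samples lo..hi inclusive."""
    xseg = xs[lo : hi + 1]
    yseg = ys[lo : hi + 1]
    return float(np.ptp(xseg) + np.ptp(yseg))


def detect_events(
    rec: GazeRecording, params: DetectionParams | None = None
) -> list[OculomotorEvent]:
    """Detect saccades then fixations; returns time-ordered, non-overlapping events.

    Saccades: maximal runs of ``speed >= velocity_threshold`` lasting at
    least ``min_saccade_ms``.  Fixations: within each remaining span, a
    greedy dispersion grouping — a window of at least ``min_fixation_ms``
    whose dispersion (range_x + range_y on smoothed positions) stays at or
    below the threshold is extended sample by sample until it would exceed
    it.  Spans qualifying as neither are left unlabeled.
    """
    params = params or DetectionParams()
    if len(rec) == 0:
        raise DetectionError("empty recording")
    if not np.any(rec.valid):
        raise DetectionError("recording has no valid samples")
    speed = compute_velocity(rec, params.smoothing_window_samples)
    xs, ys, valid = _smoothed_positions(
        rec, params.smoothing_window_samples, params.interpolate_max_gap
    )
    t = rec.t_ms
    n = len(rec)

    events: list[OculomotorEvent] = []
    is_sac = np.zeros(n, dtype=bool)

    # --- I-VT pass: velocity-threshold runs within contiguous valid segments
    above = valid & np.isfinite(speed) & (speed >= params.velocity_threshold_dps)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        if t[j] - t[i] >= params.min_saccade_ms:
            events.append(_make_event("saccade", i, j, t, xs, ys, speed))
            is_sac[i : j + 1] = True
        i = j + 1

    # --- I-DT pass over the remaining spans
    free = valid & ~is_sac
    i = 0
    while i < n:
        if not free[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and free[j + 1]:
            j += 1
        events.extend(_idt_fixations(i, j, t, xs, ys, speed, params))
        i = j + 1

    events.sort(key=lambda e: e.onset_ms)
    return events


def _make_event(
    kind: str,
    lo: int,
    hi: int,
    t: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    speed: np.ndarray,
) -> OculomotorEvent:
    seg_speed = speed[lo : hi + 1]
    peak = float(np.nanmax(seg_speed)) if np.any(np.isfinite(seg_speed)) else 0.0
    if kind == "fixation":
        # a fixation's location is its centroid; report it as both endpoints
        cx = float(np.nanmean(xs[lo : hi + 1]))
        cy = float(np.nanmean(ys[lo : hi + 1]))
        start = end = (cx, cy)
        amp = 0.0
    else:
        start = (float(xs[lo]), float(ys[lo]))
        end = (float(xs[hi]), float(ys[hi]))
        amp = math.hypot(end[0] - start[0], end[1] - start[1])
    return OculomotorEvent(
        kind=kind,
        onset_ms=float(t[lo]),
        offset_ms=float(t[hi]),
        start_xy=start,
        end_xy=end,
        amplitude_deg=amp,
        peak_velocity_dps=peak,
    )


def _idt_fixations(
    lo: int,
    hi: int,
    t: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    speed: np.ndarray,
    params: DetectionParams,
) -> list[OculomotorEvent]:
    out: list[OculomotorEvent] = []
    i = lo
    while i <= hi:
        # minimal window covering min_fixation_ms
        j = i
        while j <= hi and t[j] - t[i] < params.min_fixation_ms:
            j += 1
        if j > hi:
            break  # tail too short for a fixation
        if _dispersion(xs, ys, i, j) <= params.dispersion_threshold_deg:
            # greedy extension; cumulative dispersion from i is monotone
            seg_x = xs[i : hi + 1]
            seg_y = ys[i : hi + 1]
            disp = (
                np.maximum.accumulate(seg_x)
                - np.minimum.accumulate(seg_x)
                + np.maximum.accumulate(seg_y)
                - np.minimum.accumulate(seg_y)
            )
            j = i + int(
                np.searchsorted(disp, params.dispersion_threshold_deg, side="right") - 1
            )
            out.append(_make_event("fixation", i, j, t, xs, ys, speed))
            i = j + 1
        else:
            i += 1
    return out


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical display geometry for pixel <-> degree conversion."""

    width_px: int = 1920
    height_px: int = 1080
    width_cm: float = 47.4  # 22-inch 16:9 panel
    height_cm: float = 26.7
    distance_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_cm", "height_cm", "distance_cm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def px_to_deg(
    point_px: Sequence[float], screen: ScreenGeometry
) -> tuple[float, float]:
    """Screen-centred pixel offset -> visual angle, per axis via arctan."""
    px, py = float(point_px[0]), float(point_px[1])
    cm_x = px * screen.width_cm / screen.width_px
    cm_y = py * screen.height_cm / screen.height_px
    return (
        math.degrees(math.atan2(cm_x, screen.distance_cm)),
        math.degrees(math.atan2(cm_y, screen.distance_cm)),
    )


def deg_to_px(
    point_deg: Sequence[float], screen: ScreenGeometry
) -> tuple[float, float]:
    """Inverse of :func:`px_to_deg`."""
    dx, dy = float(point_deg[0]), float(point_deg[1])
    cm_x = screen.distance_cm * math.tan(math.radians(dx))
    cm_y = screen.distance_cm * math.tan(math.radians(dy))
    return (
        cm_x * screen.width_px / screen.width_cm,
        cm_y * screen.height_px / screen.height_cm,
    )


def events_to_dataframe(
    events: Iterable[OculomotorEvent], subject_id: str = "", trial_id: str = ""
) -> pd.DataFrame:
    """Events CSV dialect: one row per event."""
    rows = [
        {
            "subject_id": subject_id,
            "trial_id": trial_id,
            "kind": e.kind,
            "onset_ms": e.onset_ms,
            "offset_ms": e.offset_ms,
            "start_x_deg": e.start_xy[0],
            "start_y_deg": e.start_xy[1],
            "end_x_deg": e.end_xy[0],
            "end_y_deg": e.end_xy[1],
            "amplitude_deg": e.amplitude_deg,
            "peak_velocity_dps": e.peak_velocity_dps,
        }
        for e in events
    ]
    return pd.DataFrame(rows)
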