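"""Windowed fatigue-feature measurements from raw per-frame/per-sample streams.

Eight features are computed per recognition window:

facial (60 s windows, from camera frames)
    * ``bf``   blink frequency — fraction of frames with eyes closed
    * ``ecd``  eye-closed duration — fraction of frames inside closed-eye
      runs lasting at least 2 s (a PERCLOS-like measure)
    * ``meol`` mean eye-opened level — mean eyelid aperture in pixels
    * ``yf``   yawning frequency — fraction of frames whose mouth
      height/width ratio exceeds a threshold

vehicle (10 s windows, steering / lane / GPS)
    * ``pns``  percentage of non-steering — fraction of samples with
      steering-wheel angular velocity within a dead band (±0.1 deg/s)
    * ``sdsa`` standard deviation of steering angle (population SD, degrees)
    * ``fald`` frequency of abnormal lane deviation — fraction of frames
      whose lane-line slope-angle ratio indicates departure
    * ``sdvs`` standard deviation of vehicle speed (population SD, km/h)

``windowize`` aligns the two time bases: one recognition step per 60 s, with
the 10 s vehicle features evaluated on the final 10 s of each minute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, InvalidInputError, InvalidWindowError

__all__ = [
    "FrameStream",
    "VehicleStream",
    "FeatureConfig",
    "FeatureWindow",
    "FEATURE_NAMES",
    "FACIAL_FEATURES",
    "VEHICLE_FEATURES",
    "blink_frequency",
    "eye_closed_duration",
    "mean_eye_opened_level",
    "yawning_frequency",
    "percent_non_steering",
    "steering_angle_sd",
    "lane_deviation_frequency",
    "speed_sd",
    "windowize",
    "read_frame_stream",
    "read_vehicle_stream",
    "windows_to_frame",
]

logger = logging.getLogger(__name__)

FACIAL_FEATURES = ("bf", "ecd", "meol", "yf")
VEHICLE_FEATURES = ("pns", "sdsa", "fald", "sdvs")
FEATURE_NAMES = FACIAL_FEATURES + VEHICLE_FEATURES

FACIAL_WINDOW_S = 60.0
VEHICLE_WINDOW_S = 10.0


def _check_monotone(t: np.ndarray, name: str) -> None:
    if t.size and np.any(np.diff(t) <= 0):
        raise InvalidInputError(f"{name} timestamps must be strictly increasing")


@dataclass
class FrameStream:
    """Per-frame facial measurements on a common time base.

    ``eyelid_height`` is the aperture between upper and lower eyelids in
    pixels; ``mouth_height``/``mouth_width`` are the lip-to-lip and
    corner-to-corner mouth extents in pixels.
    """

    timestamps: np.ndarray
    eye_closed: np.ndarray
    eyelid_height: np.ndarray
    mouth_height: np.ndarray
    mouth_width: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.eye_closed = np.asarray(self.eye_closed, dtype=bool)
        self.eyelid_height = np.asarray(self.eyelid_height, dtype=float)
        self.mouth_height = np.asarray(self.mouth_height, dtype=float)
        self.mouth_width = np.asarray(self.mouth_width, dtype=float)
        n = self.timestamps.size
        for name in ("eye_closed", "eyelid_height", "mouth_height", "mouth_width"):
            if getattr(self, name).size != n:
                raise InvalidInputError(f"{name} length differs from timestamps")
        _check_monotone(self.timestamps, "frame")
        if self.frame_rate <= 0:
            raise InvalidInputError("frame_rate must be positive")
        for name in ("eyelid_height", "mouth_height", "mouth_width"):
            if np.any(getattr(self, name) < 0):
                raise InvalidInputError(f"{name} must be non-negative")

    def __len__(self) -> int:
        return self.timestamps.size

    def slice(self, start: float, stop: float) -> "FrameStream":
        """Frames with timestamps in the half-open interval [start, stop)."""
        sel = (self.timestamps >= start) & (self.timestamps < stop)
        return FrameStream(
            self.timestamps[sel],
            self.eye_closed[sel],
            self.eyelid_height[sel],
            self.mouth_height[sel],
            self.mouth_width[sel],
            self.frame_rate,
        )


@dataclass
class VehicleStream:
    """Steering, lane-geometry and speed samples on a common time base.

    ``lane_theta_left`` / ``lane_theta_right`` are the slope angles of the
    detected left/right lane lines in radians, both in (0, pi).  If
    ``steer_rate`` is absent it is estimated as the first difference of
    ``steer_angle`` divided by the sampling interval.
    """

    timestamps: np.ndarray
    steer_angle: np.ndarray
    lane_theta_left: np.ndarray
    lane_theta_right: np.ndarray
    speed: np.ndarray
    steer_rate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.steer_angle = np.asarray(self.steer_angle, dtype=float)
        self.lane_theta_left = np.asarray(self.lane_theta_left, dtype=float)
        self.lane_theta_right = np.asarray(self.lane_theta_right, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        n = self.timestamps.size
        for name in ("steer_angle", "lane_theta_left", "lane_theta_right", "speed"):
            if getattr(self, name).size != n:
                raise InvalidInputError(f"{name} length differs from timestamps")
        _check_monotone(self.timestamps, "vehicle")
        if np.any(self.speed < 0):
            raise InvalidInputError("speeds must be non-negative")
        for name in ("lane_theta_left", "lane_theta_right"):
            v = getattr(self, name)
            if v.size and (np.any(v <= 0) or np.any(v >= np.pi)):
                raise InvalidInputError(f"{name} must lie in (0, pi)")
        if self.steer_rate is None:
            if n >= 2:
                dt = np.diff(self.timestamps)
                rate = np.diff(self.steer_angle) / dt
                # first-difference estimator: prepend the first rate so the
                # series keeps the stream's length
                self.steer_rate = np.concatenate([[rate[0]], rate])
            else:
                self.steer_rate = np.zeros(n)
        else:
            self.steer_rate = np.asarray(self.steer_rate, dtype=float)
            if self.steer_rate.size != n:
                raise InvalidInputError("steer_rate length differs from timestamps")

    def __len__(self) -> int:
        return self.timestamps.size

    def slice(self, start: float, stop: float) -> "VehicleStream":
        sel = (self.timestamps >= start) & (self.timestamps < stop)
        return VehicleStream(
            self.timestamps[sel],
            self.steer_angle[sel],
            self.lane_theta_left[sel],
            self.lane_theta_right[sel],
            self.speed[sel],
            steer_rate=self.steer_rate[sel],
        )


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable constants of the feature definitions.

    ``yawn_threshold`` is the mouth height/width ratio above which a frame
    counts as yawning; ``nonsteer_band`` the angular-velocity dead band in
    deg/s; ``ecd_min_closure`` the minimum closed-run length in seconds;
    ``lambda_left`` / ``lambda_right`` the lane-departure thresholds on the
    slope-angle ratio.  ``lane_rule`` selects the symmetric departure rule
    (``xi > lambda_left`` or ``xi < 1/lambda_right``) or the literal
    one-sided disjunction (``xi > lambda_left or xi > lambda_right``).
    """

    yawn_threshold: float = 0.5
    nonsteer_band: float = 0.1
    ecd_min_closure: float = 2.0
    lambda_left: float = 1.2
    lambda_right: float = 1.2
    lane_rule: str = "symmetric"

    def __post_init__(self) -> None:
        if self.yawn_threshold < 0:
            raise InvalidInputError("yawn_threshold must be non-negative")
        if self.nonsteer_band <= 0 or self.ecd_min_closure <= 0:
            raise InvalidInputError("nonsteer_band and ecd_min_closure must be positive")
        if self.lane_rule not in ("symmetric", "literal"):
            raise InvalidInputError("lane_rule must be 'symmetric' or 'literal'")


@dataclass(frozen=True)
class FeatureWindow:
    """The eight windowed measurements for one recognition step."""

    bf: float
    ecd: float
    meol: float
    yf: float
    pns: float
    sdsa: float
    fald: float
    sdvs: float
    window_start: float = 0.0

    def facial_vector(self) -> np.ndarray:
        return np.array([self.bf, self.ecd, self.yf])

    def vehicle_vector(self) -> np.ndarray:
        return np.array([self.pns, self.sdsa, self.fald, self.sdvs])

    def as_dict(self) -> dict[str, float]:
        return {
            "window_start": self.window_start,
            **{name: getattr(self, name) for name in FEATURE_NAMES},
        }


def _require_nonempty(n: int) -> None:
    if n == 0:
        raise InvalidWindowError("empty measurement window")


def blink_frequency(frames: FrameStream) -> float:
    """Fraction of frames in which the eyes are detected as closed."""
    _require_nonempty(len(frames))
    return float(np.count_nonzero(frames.eye_closed)) / len(frames)


def eye_closed_duration(frames: FrameStream, cfg: FeatureConfig | None = None) -> float:
    """Fraction of frames inside maximal closed-eye runs of >= 2 s.

    A maximal run of consecutive closed frames contributes all of its frames
    when its duration (run length / frame rate) reaches ``ecd_min_closure``;
    shorter runs contribute nothing.
    """
    cfg = cfg or FeatureConfig()
    _require_nonempty(len(frames))
    closed = frames.eye_closed.astype(int)
    # run-length encode the closed mask
    boundaries = np.flatnonzero(np.diff(closed) != 0) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [closed.size]])
    min_frames = cfg.ecd_min_closure * frames.frame_rate
    n_c = sum(
        int(e - s)
        for s, e in zip(starts, ends)
        if closed[s] and (e - s) >= min_frames
    )
    return n_c / len(frames)


def mean_eye_opened_level(frames: FrameStream) -> float:
    """Arithmetic mean of the eyelid aperture (pixels) over the window."""
    _require_nonempty(len(frames))
    return float(frames.eyelid_height.mean())


def yawning_frequency(frames: FrameStream, cfg: FeatureConfig | None = None) -> float:
    """Fraction of frames whose mouth-opening ratio h/w reaches the threshold.

    Frames with zero mouth width cannot yield a ratio; they are excluded from
    both numerator and denominator and logged.
    """
    cfg = cfg or FeatureConfig()
    _require_nonempty(len(frames))
    valid = frames.mouth_width > 0
    n_excluded = int(np.count_nonzero(~valid))
    if n_excluded:
        logger.warning("yawning_frequency: excluded %d zero-width frames", n_excluded)
    if not np.any(valid):
        raise DegenerateGeometryError("no frame has positive mouth width")
    ratio = frames.mouth_height[valid] / frames.mouth_width[valid]
    return float(np.count_nonzero(ratio >= cfg.yawn_threshold)) / int(valid.sum())


def percent_non_steering(veh: VehicleStream, cfg: FeatureConfig | None = None) -> float:
    """Fraction of samples with |steering angular velocity| inside the dead band."""
    cfg = cfg or FeatureConfig()
    _require_nonempty(len(veh))
    return float(np.count_nonzero(np.abs(veh.steer_rate) <= cfg.nonsteer_band)) / len(veh)


def steering_angle_sd(veh: VehicleStream) -> float:
    """Population standard deviation (1/N normalisation) of the steering angle."""
    _require_nonempty(len(veh))
    return float(np.std(veh.steer_angle))


def lane_deviation_frequency(veh: VehicleStream, cfg: FeatureConfig | None = None) -> float:
    """Fraction of frames whose lane-line geometry indicates abnormal departure.

    The departure index is ``xi = (pi/2 - theta_L) / (theta_R - pi/2)``;
    symmetric lane lines give xi = 1.  Under the default symmetric rule a
    frame deviates when ``xi > lambda_left`` (drifting left) or
    ``xi < 1/lambda_right`` (drifting right); the ``literal`` rule instead
    fires when xi exceeds either threshold.  Frames with a vertical right
    lane line (theta_R = pi/2, xi undefined) are excluded and logged.
    """
    cfg = cfg or FeatureConfig()
    _require_nonempty(len(veh))
    denom = veh.lane_theta_right - np.pi / 2.0
    valid = np.abs(denom) > 1e-12
    n_excluded = int(np.count_nonzero(~valid))
    if n_excluded:
        logger.warning("lane_deviation_frequency: excluded %d indeterminate frames", n_excluded)
    if not np.any(valid):
        raise DegenerateGeometryError("no frame has a well-defined departure index")
    xi = (np.pi / 2.0 - veh.lane_theta_left[valid]) / denom[valid]
    if cfg.lane_rule == "symmetric":
        deviating = (xi > cfg.lambda_left) | (xi < 1.0 / cfg.lambda_right)
    else:
        deviating = (xi > cfg.lambda_left) | (xi > cfg.lambda_right)
    return float(np.count_nonzero(deviating)) / int(valid.sum())


def speed_sd(veh: VehicleStream) -> float:
    """Population standard deviation (1/N normalisation) of vehicle speed."""
    _require_nonempty(len(veh))
    return float(np.std(veh.speed))


def windowize(
    frames: FrameStream,
    veh: VehicleStream,
    cfg: FeatureConfig | None = None,
) -> list[FeatureWindow]:
    """Cut the streams into contiguous 60 s recognition windows.

    Facial and lane features use the whole minute; the 10 s steering/speed
    features (pns, sdsa, sdvs) use its final 10 s sub-window.  Incomplete
    trailing minutes are dropped.  Raises on streams with no overlap.
    """
    cfg = cfg or FeatureConfig()
    if len(frames) == 0 or len(veh) == 0:
        raise InvalidInputError("both streams must be nonempty")
    t0 = max(frames.timestamps[0], veh.timestamps[0])
    # a stream covers one sampling interval past its last timestamp
    f_dt = 1.0 / frames.frame_rate
    v_dt = float(np.median(np.diff(veh.timestamps))) if len(veh) > 1 else 0.0
    t1 = min(frames.timestamps[-1] + f_dt, veh.timestamps[-1] + v_dt)
    if t1 <= t0:
        raise InvalidInputError("streams do not overlap in time")
    out: list[FeatureWindow] = []
    start = t0
    while start + FACIAL_WINDOW_S <= t1 + 1e-9:
        stop = start + FACIAL_WINDOW_S
        f = frames.slice(start, stop)
        v_minute = veh.slice(start, stop)
        v_tail = veh.slice(stop - VEHICLE_WINDOW_S, stop)
        if len(f) == 0 or len(v_minute) == 0 or len(v_tail) == 0:
            logger.warning("windowize: skipped window at %.1f s (missing samples)", start)
            start = stop
            continue
        out.append(
            FeatureWindow(
                bf=blink_frequency(f),
                ecd=eye_closed_duration(f, cfg),
                meol=mean_eye_opened_level(f),
                yf=yawning_frequency(f, cfg),
                pns=percent_non_steering(v_tail, cfg),
                sdsa=steering_angle_sd(v_tail),
                fald=lane_deviation_frequency(v_minute, cfg),
                sdvs=speed_sd(v_tail),
                window_start=float(start),
            )
        )
        start = stop
    return out


# ---------------------------------------------------------------------------
# CSV exchange


def read_frame_stream(path, frame_rate: float | None = None) -> FrameStream:
    """Facial stream from CSV columns (t, eye_closed, eyelid_h, mouth_h, mouth_w)."""
    df = pd.read_csv(path)
    t = df["t"].to_numpy(dtype=float)
    if frame_rate is None:
        if t.size < 2:
            raise InvalidInputError("cannot infer frame rate from fewer than 2 frames")
        frame_rate = 1.0 / float(np.median(np.diff(t)))
    return FrameStream(
        t,
        df["eye_closed"].to_numpy(dtype=bool),
        df["eyelid_h"].to_numpy(dtype=float),
        df["mouth_h"].to_numpy(dtype=float),
        df["mouth_w"].to_numpy(dtype=float),
        frame_rate,
    )


def read_vehicle_stream(path) -> VehicleStream:
    """Vehicle stream from CSV columns (t, steer_angle, theta_L, theta_R, speed[, steer_rate])."""
    df = pd.read_csv(path)
    rate = df["steer_rate"].to_numpy(dtype=float) if "steer_rate" in df else None
    return VehicleStream(
        df["t"].to_numpy(dtype=float),
        df["steer_angle"].to_numpy(dtype=float),
        df["theta_L"].to_numpy(dtype=float),
        df["theta_R"].to_numpy(dtype=float),
        df["speed"].to_numpy(dtype=float),
        steer_rate=rate,
    )


def windows_to_frame(windows: Sequence[FeatureWindow]) -> pd.DataFrame:
    """Feature table with one row per window (window_start + the eight features)."""
    return pd.DataFrame([w.as_dict() for w in windows])
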