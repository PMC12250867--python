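"""Injury localization from smoothed pulse-pressure pullback series.

During a constant-rate catheter pullback, each pressure sensor crosses
the injury at a different time; the crossing shows up as a localized
drop in that sensor's smoothed pulse-pressure (PP) series. The injury
time is detected per sensor as the point of maximum negative change
(most negative first derivative of the filtered PP series), the
per-sensor times are corrected for the sensors' known offsets along the
catheter and averaged, and the fused crossing time is converted to a
centerline position via the pullback rate.

Pullbacks are classified as baseline (PP rising as the catheter moves
distally — pulse-pressure amplification, no hemorrhage) or injury
(PP falling) from the sign of the median per-sensor PP slope, and
recordings whose mean arterial pressure is below a quality threshold
(default 20 mmHg) are flagged LOW_MAP and left unclassified: near
circulatory collapse the proximal/distal PP contrast vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .beat_features import (
    DEFAULT_GRID_STEP_S,
    DEFAULT_SMOOTH_WINDOW_S,
    BeatFeatureSeries,
    detect_beats,
    extract_beat_features,
    preprocess_signal,
    resample_feature_series,
    smooth_feature_series,
)
from .waveform_io import INJURY_CROSSING_LABEL, PressureRecording, find_annotation

__all__ = [
    "SensorLayout",
    "PullbackTrack",
    "LocalizeParams",
    "LocalizationResult",
    "changepoint_time",
    "fuse_estimates",
    "classify_pullback",
    "localize",
    "localize_profile",
]

LOW_MAP_FLAG = "LOW_MAP"


@dataclass
class SensorLayout:
    """Signed sensor offsets (cm) from the catheter reference point.

    The reference point is the midpoint of sensors 2 and 3 for the
    default 4-sensor catheter; offsets are positive toward the tip,
    which sits at the most proximal aortic position. A sensor with
    offset ``d`` therefore lies at centerline position ``ref − d`` and
    crosses the injury ``d / rate`` seconds after the reference point.
    """

    offsets: tuple[float, ...] = (7.5, 2.5, -2.5, -7.5)

    @classmethod
    def equispaced(cls, sensor_count: int, spacing: float) -> "SensorLayout":
        """Symmetric layout of ``sensor_count`` sensors ``spacing`` cm apart."""
        return cls(
            tuple(((sensor_count - 1) / 2.0 - i) * spacing for i in range(sensor_count))
        )


@dataclass
class PullbackTrack:
    """Constant-rate pullback kinematics of the reference point.

    ``start_position`` is the reference point's centerline position (cm)
    at t=0; position increases distally at ``rate`` cm/s.
    """

    rate: float
    start_position: float

    def position(self, t: float) -> float:
        return self.start_position + self.rate * t


@dataclass
class LocalizeParams:
    grid_step: float = DEFAULT_GRID_STEP_S
    smooth_window: float = DEFAULT_SMOOTH_WINDOW_S
    map_threshold: float = 20.0  # mmHg quality gate
    slope_eps: float = 0.01  # mmHg/s dead-band for baseline/injury call


@dataclass
class LocalizationResult:
    per_sensor_time: dict[int, float | None]
    fused_time: float | None
    fused_position: float | None
    classification: str  # baseline | injury | indeterminate
    map_mean: float
    flags: set[str] = field(default_factory=set)
    time_error: float | None = None  # fused − annotated (s)
    position_error: float | None = None  # time_error × rate (cm)


def changepoint_time(grid_time: np.ndarray, values: np.ndarray) -> float | None:
    """Time of maximum negative change of a series on a uniform grid.

    The change is the central first difference. A boxcar-filtered step
    has a *plateau* of equally negative differences spanning the filter
    width, so exact ties are resolved to the center of the earliest
    minimal plateau — which places an ideal smoothed step-down exactly
    at its midpoint. Returns None when no change is negative (monotone
    nondecreasing series).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 grid points")
    deriv = (values[2:] - values[:-2]) / 2.0  # constant grid step: scale-free argmin
    dmin = deriv.min()
    if dmin >= 0:
        return None
    tied = np.flatnonzero(deriv <= dmin + 1e-12 * max(1.0, abs(dmin)))
    run_end = tied[0]
    for k in tied[1:]:
        if k == run_end + 1:
            run_end = k
        else:
            break
    k = (tied[0] + run_end) // 2
    return float(grid_time[1 + k])


def fuse_estimates(
    per_sensor_time: dict[int, float], layout: SensorLayout, track: PullbackTrack
) -> tuple[float, float]:
    """Average offset-corrected per-sensor crossing times.

    Sensor *i* (1-based) at offset ``d_i`` crosses the injury
    ``d_i/rate`` seconds after the reference point, so each reported
    time is corrected by ``−d_i/rate`` before averaging. For the
    symmetric default layout with all sensors reporting this equals the
    plain average of the raw timestamps. Returns (fused_time,
    fused_position).
    """
    if not per_sensor_time:
        raise ValueError("no per-sensor estimates to fuse")
    corrected = [
        t - layout.offsets[i - 1] / track.rate for i, t in per_sensor_time.items()
    ]
    fused_time = float(np.mean(corrected))
    return fused_time, track.position(fused_time)


def classify_pullback(
    series_list: list[BeatFeatureSeries],
    map_mean: float,
    map_threshold: float = 20.0,
    slope_eps: float = 0.01,
) -> tuple[str, set[str]]:
    """Baseline/injury call from the median per-sensor smoothed-PP slope.

    Baseline pullbacks show rising PP (distal amplification), injury
    pullbacks falling PP. Below ``map_threshold`` the PP contrast is
    physiologically negligible, so the recording is flagged LOW_MAP and
    left indeterminate regardless of slope.
    """
    if not series_list:
        raise ValueError("need at least one smoothed PP series")
    flags: set[str] = set()
    if map_mean < map_threshold:
        flags.add(LOW_MAP_FLAG)
        return "indeterminate", flags
    slopes = []
    for s in series_list:
        t, v = s.grid_time, s.features["PP"]
        slopes.append(np.polyfit(t, v, 1)[0])
    med = float(np.median(slopes))
    if med < -slope_eps:
        return "injury", flags
    if med > slope_eps:
        return "baseline", flags
    return "indeterminate", flags


def _layout_and_track(rec: PressureRecording) -> tuple[SensorLayout, PullbackTrack]:
    m = rec.metadata
    layout = SensorLayout.equispaced(m.sensor_count, m.sensor_spacing)
    # metadata start_position is sensor 1 (offset d_1); reference = sensor1 + d_1
    ref_start = m.start_position + layout.offsets[0]
    return layout, PullbackTrack(rate=m.pullback_rate, start_position=ref_start)


def localize(rec: PressureRecording, params: LocalizeParams | None = None) -> LocalizationResult:
    """Full localization pipeline on one pullback recording.

    Runs beat detection, per-beat feature extraction, uniform-grid
    resampling and smoothing per sensor, finds each sensor's maximum
    negative PP change, fuses the offset-corrected times, classifies the
    pullback, and — when a ground-truth crossing annotation is present —
    reports the signed time and position error.
    """
    params = params or LocalizeParams()
    if rec.metadata.mode != "pullback":
        raise ValueError("localize requires a pullback recording")
    fs = rec.metadata.sampling_rate

    # grid points within this many points of either end lack full
    # smoothing support (and the final beat's window is truncated by the
    # recording edge), so the change-point scan skips them
    guard = int(round(params.smooth_window / params.grid_step / 2)) + 1

    series_list: list[BeatFeatureSeries] = []
    per_sensor: dict[int, float | None] = {}
    for i in range(1, rec.metadata.sensor_count + 1):
        sig = preprocess_signal(rec.channel(i), fs)
        try:
            peaks = detect_beats(sig, fs)
            beats = extract_beat_features(sig, peaks, fs, sensor_index=i)
            series = resample_feature_series(beats, params.grid_step)
        except ValueError:
            per_sensor[i] = None
            continue
        if len(series.grid_time) < 3:
            per_sensor[i] = None
            continue
        smoothed = smooth_feature_series(series, params.smooth_window)
        series_list.append(smoothed)
        t, v = smoothed.grid_time, smoothed.features["PP"]
        if len(t) > 2 * guard + 3:
            t, v = t[guard:-guard], v[guard:-guard]
        per_sensor[i] = changepoint_time(t, v)

    if not series_list:
        raise RuntimeError("beat detection failed on all channels")

    map_mean = float(np.mean(rec.pressure))
    classification, flags = classify_pullback(
        series_list, map_mean, params.map_threshold, params.slope_eps
    )

    layout, track = _layout_and_track(rec)
    present = {i: t for i, t in per_sensor.items() if t is not None}
    fused_time = fused_position = None
    if present:
        fused_time, fused_position = fuse_estimates(present, layout, track)

    time_error = position_error = None
    ann = find_annotation(rec, INJURY_CROSSING_LABEL)
    if ann is not None and fused_time is not None:
        time_error = fused_time - ann.time
        position_error = time_error * track.rate
    return LocalizationResult(
        per_sensor_time=per_sensor,
        fused_time=fused_time,
        fused_position=fused_position,
        classification=classification,
        map_mean=map_mean,
        flags=flags,
        time_error=time_error,
        position_error=position_error,
    )


def localize_profile(
    positions: np.ndarray, pp: np.ndarray, smooth_window_cm: float = 2.0
) -> float:
    """Injury position from a centerline PP(x) profile.

    Applies the same filtered maximum-negative-derivative detector used
    on pullback time series, but directly in space: smooth PP(x) with a
    centered moving average of width ``smooth_window_cm`` and return the
    position of the most negative central difference.
    """
    from .beat_features import moving_average

    positions = np.asarray(positions, dtype=float)
    dx = positions[1] - positions[0]
    half = int(round(smooth_window_cm / dx / 2))
    sm = moving_average(np.asarray(pp, dtype=float), half)
    t = changepoint_time(positions, sm)
    if t is None:
        raise ValueError("profile has no negative change")
    return t
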