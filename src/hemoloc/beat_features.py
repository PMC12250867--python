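"""Per-beat feature extraction from arterial pressure waveforms.

The pipeline is: detect systolic peaks, delimit beats at the diastolic
onsets between peaks, extract per-beat features — peak-to-peak interval
(PPI), systolic pressure (SBP, beat maximum), diastolic pressure (DBP,
beat minimum), pulse pressure (PP = SBP − DBP) and beat-mean pressure
(MAP) — then resample the irregular per-beat series onto a uniform time
grid, smooth with a zero-phase moving average, and optionally normalize
each feature by its recording-wide maximum.

The beat detector uses an adaptive threshold (rolling median plus
0.4 × rolling inter-quartile range over a 4 s window, computed on a
decimated copy of the signal) with a 0.25 s refractory period, so that it
tracks the large mean-pressure drifts seen during active hemorrhage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

__all__ = [
    "Beat",
    "BeatFeatureSeries",
    "preprocess_signal",
    "detect_beats",
    "extract_beat_features",
    "resample_feature_series",
    "smooth_feature_series",
    "normalize_feature_series",
    "feature_table",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("PPI", "SBP", "DBP", "PP", "MAP")

#: minimum peak-to-peak spacing (s); caps implied heart rate at 240 bpm
REFRACTORY_S = 0.25
#: adaptive-threshold window (s)
THRESHOLD_WINDOW_S = 4.0
#: IQR multiple above the rolling median for peak candidacy
THRESHOLD_IQR_GAIN = 0.4
#: signals with less than this peak-to-trough range (mmHg) are treated as flat
FLAT_RANGE_MMHG = 1.0

DEFAULT_GRID_STEP_S = 0.25
DEFAULT_SMOOTH_WINDOW_S = 3.0
#: waveform pre-filter width (s): suppresses sensor noise well below the
#: pulse band before per-beat extrema are read off
PREFILTER_WINDOW_S = 0.025


@dataclass
class Beat:
    """Features of a single cardiac beat on one sensor.

    ``ppi`` is the interval to the previous systolic peak and is NaN for
    the first detected beat.
    """

    sensor_index: int
    peak_time: float
    onset_time: float
    sbp: float
    dbp: float
    pp: float
    map: float
    ppi: float


@dataclass
class BeatFeatureSeries:
    """Per-beat features of one sensor, with a uniform-grid resampling.

    ``features`` maps a feature name to its series on ``grid_time``;
    ``smoothed``/``normalized`` record which variants have been applied.
    """

    sensor_index: int
    beats: list[Beat]
    grid_time: np.ndarray
    features: dict[str, np.ndarray]
    grid_step: float
    smoothed: bool = False
    normalized: bool = False


def preprocess_signal(
    signal: np.ndarray, sampling_rate: float, window_s: float = PREFILTER_WINDOW_S
) -> np.ndarray:
    """Light zero-phase smoothing of the raw waveform (default 25 ms).

    The pulse band (< ~15 Hz) passes essentially untouched while
    sample-level sensor noise on the systolic/diastolic extrema is cut
    by roughly the square root of the window length.
    """
    half = int(round(window_s * sampling_rate / 2))
    return moving_average(np.asarray(signal, dtype=float), half)


def _adaptive_threshold(signal: np.ndarray, fs: float) -> np.ndarray:
    """Rolling median + IQR-based peak-candidacy threshold, full length.

    Percentiles are computed on a ~100 Hz decimated copy (the threshold
    is a slowly varying envelope; sample-rate precision buys nothing) and
    interpolated back to the original grid.
    """
    dec = max(1, int(round(fs / 100.0)))
    s = signal[::dec]
    w = max(3, int(round(THRESHOLD_WINDOW_S * fs / dec)))
    ser = pd.Series(s)
    med = ser.rolling(w, center=True, min_periods=1).median().to_numpy()
    q75 = ser.rolling(w, center=True, min_periods=1).quantile(0.75).to_numpy()
    q25 = ser.rolling(w, center=True, min_periods=1).quantile(0.25).to_numpy()
    thr = med + THRESHOLD_IQR_GAIN * (q75 - q25)
    idx_dec = np.arange(len(s)) * dec
    return np.interp(np.arange(len(signal)), idx_dec, thr)


def detect_beats(signal: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Systolic peak times (s) of an arterial pressure signal.

    Returns a strictly increasing array of peak times. A near-flat
    signal (range < 1 mmHg) yields an empty array; a signal shorter than
    2 s is rejected.
    """
    signal = np.asarray(signal, dtype=float)
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be > 0")
    if len(signal) < 2 * sampling_rate:
        raise ValueError("signal shorter than 2 s")
    if np.ptp(signal) < FLAT_RANGE_MMHG:
        return np.array([])
    thr = _adaptive_threshold(signal, sampling_rate)
    distance = max(1, int(round(REFRACTORY_S * sampling_rate)))
    peaks, _ = find_peaks(signal, height=thr, distance=distance)
    return peaks / sampling_rate


def extract_beat_features(
    signal: np.ndarray, peaks: np.ndarray, sampling_rate: float, sensor_index: int = 1
) -> list[Beat]:
    """Per-beat features given the signal and its systolic peak times.

    Each beat spans from its onset (the pressure minimum between the
    previous peak and this one; signal start for the first beat) to the
    next beat's onset (signal end for the last). SBP/DBP/MAP are the
    window max/min/mean; PP = SBP − DBP.
    """
    signal = np.asarray(signal, dtype=float)
    peaks = np.asarray(peaks, dtype=float)
    if len(peaks) < 2:
        return []
    pk_idx = np.round(peaks * sampling_rate).astype(int)
    pk_idx = np.clip(pk_idx, 0, len(signal) - 1)

    onset_idx = np.empty(len(pk_idx), dtype=int)
    onset_idx[0] = int(np.argmin(signal[: pk_idx[0] + 1]))
    for k in range(1, len(pk_idx)):
        lo, hi = pk_idx[k - 1], pk_idx[k]
        onset_idx[k] = lo + int(np.argmin(signal[lo : hi + 1]))

    beats: list[Beat] = []
    for k in range(len(pk_idx)):
        w_lo = onset_idx[k]
        w_hi = onset_idx[k + 1] if k + 1 < len(pk_idx) else len(signal)
        window = signal[w_lo:w_hi]
        sbp = float(np.max(window))
        dbp = float(np.min(window))
        beats.append(
            Beat(
                sensor_index=sensor_index,
                peak_time=float(peaks[k]),
                onset_time=w_lo / sampling_rate,
                sbp=sbp,
                dbp=dbp,
                pp=sbp - dbp,
                map=float(np.mean(window)),
                ppi=float(peaks[k] - peaks[k - 1]) if k else float("nan"),
            )
        )
    return beats


def resample_feature_series(
    beats: list[Beat], grid_step: float = DEFAULT_GRID_STEP_S
) -> BeatFeatureSeries:
    """Linearly interpolate per-beat features onto a uniform time grid.

    The grid spans [first beat, last beat] — no extrapolation. PPI is
    undefined for the first beat, so its interpolation starts at the
    second beat's peak time (held constant before it within the grid).
    """
    if len(beats) < 2:
        raise ValueError("need at least 2 beats to resample")
    t = np.array([b.peak_time for b in beats])
    t0 = np.ceil(t[0] / grid_step) * grid_step
    grid = np.arange(t0, t[-1] + 1e-9, grid_step)
    values = {
        "SBP": np.array([b.sbp for b in beats]),
        "DBP": np.array([b.dbp for b in beats]),
        "PP": np.array([b.pp for b in beats]),
        "MAP": np.array([b.map for b in beats]),
        "PPI": np.array([b.ppi for b in beats]),
    }
    features = {}
    for name, v in values.items():
        ok = ~np.isnan(v)
        features[name] = np.interp(grid, t[ok], v[ok])
    return BeatFeatureSeries(
        sensor_index=beats[0].sensor_index,
        beats=beats,
        grid_time=grid,
        features=features,
        grid_step=grid_step,
    )


def moving_average(values: np.ndarray, half_width: int) -> np.ndarray:
    """Zero-phase centered moving average, edges by window truncation."""
    if half_width == 0:
        return values.copy()
    kernel = np.ones(2 * half_width + 1)
    num = np.convolve(values, kernel, mode="same")
    den = np.convolve(np.ones_like(values), kernel, mode="same")
    return num / den


def smooth_feature_series(
    series: BeatFeatureSeries, window: float = DEFAULT_SMOOTH_WINDOW_S
) -> BeatFeatureSeries:
    """Zero-phase moving average of width ``window`` seconds per feature.

    The realized window is the odd grid-point count nearest ``window``;
    edges are handled by truncating the window, so constants pass
    through unchanged everywhere.
    """
    if window < series.grid_step:
        raise ValueError("smoothing window shorter than grid step")
    half = int(round(window / series.grid_step / 2))
    features = {k: moving_average(v, half) for k, v in series.features.items()}
    return replace(series, features=features, smoothed=True)


def normalize_feature_series(series: BeatFeatureSeries) -> BeatFeatureSeries:
    """Divide every feature by its recording-wide maximum for this sensor.

    After normalization the maximum of each feature series is exactly 1;
    the operation is idempotent up to floating-point rounding.
    """
    features = {}
    for name, v in series.features.items():
        vmax = np.nanmax(v)
        if not vmax > 0:
            raise ValueError(f"{name}: non-positive maximum {vmax}, cannot normalize")
        features[name] = v / vmax
    return replace(series, features=features, normalized=True)


def feature_table(series_list: list[BeatFeatureSeries]) -> pd.DataFrame:
    """Tidy table (sensor, time, feature, value, variant) for export."""
    rows = []
    for s in series_list:
        variant = ("smoothed" if s.smoothed else "raw") + (
            "+normalized" if s.normalized else ""
        )
        for name, v in s.features.items():
            rows.append(
                pd.DataFrame(
                    {
                        "sensor": s.sensor_index,
                        "time": s.grid_time,
                        "feature": name,
                        "value": v,
                        "variant": variant,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
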