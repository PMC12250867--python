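"""On-disk dialect for multichannel intra-aortic pressure recordings.

A recording lives in three sibling text files sharing a stem:

``<stem>.csv``
    Comma-separated table ``time,p1..pN`` — time in seconds on a uniform
    grid starting at 0, pressures in mmHg. Channel ``p1`` is the catheter
    tip, the most proximal aortic position; positions increase distally.
``<stem>.meta.json``
    Recording metadata (subject, phase, acquisition mode, sampling rate,
    sensor geometry, pullback kinematics).
``<stem>.events.csv``
    Event annotations ``label,time,resolution`` (e.g. the time the
    catheter reference point crossed the injury, with its truth
    quantization). Absent or empty when there are no annotations.

All values are stored in base units (s, mmHg, cm, cm/s) at full double
precision, so a write/read round trip is value-exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RecordingMetadata",
    "EventAnnotation",
    "PressureRecording",
    "RecordingFormatError",
    "read_recording",
    "write_recording",
    "validate_recording",
]

#: label used for ground-truth injury-crossing annotations
INJURY_CROSSING_LABEL = "midpoint_crossed_injury"

_PHASES = ("baseline", "injury")
_MODES = ("static", "pullback")
_UNITS = ("mmHg",)

#: time-grid uniformity tolerance (s)
_TIME_TOL = 1e-6


class RecordingFormatError(ValueError):
    """Raised when on-disk data violates the recording dialect."""


@dataclass
class RecordingMetadata:
    """Acquisition metadata for one recording.

    ``start_position`` is the centerline position (cm) of sensor 1 (the
    catheter tip) at t=0; the centerline coordinate is 0 at the
    subclavian-adjacent pullback start and increases distally. For
    ``mode="pullback"``, ``pullback_rate`` is the constant distal
    withdrawal speed in cm/s.
    """

    subject_id: str
    phase: str  # baseline | injury
    mode: str  # static | pullback
    sampling_rate: float  # samples/s
    sensor_count: int
    sensor_spacing: float  # cm
    start_position: float  # cm, sensor 1 at t=0
    pullback_rate: float | None = None  # cm/s, pullback mode only
    units: str = "mmHg"


@dataclass
class EventAnnotation:
    label: str
    time: float  # s, within the recording span
    resolution: float = 0.0  # s, truth quantization (>= 0)


@dataclass
class PressureRecording:
    """Multichannel pressure time series plus metadata and annotations.

    ``pressure`` has shape ``(n_samples, sensor_count)``; column *i* is
    sensor *i+1*. ``time`` is a uniform grid from 0 with step
    ``1/sampling_rate``.
    """

    metadata: RecordingMetadata
    time: np.ndarray
    pressure: np.ndarray
    annotations: list[EventAnnotation] = field(default_factory=list)

    @property
    def duration(self) -> float:
        return float(self.time[-1]) if len(self.time) else 0.0

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def channel(self, sensor_index: int) -> np.ndarray:
        """Pressure series of 1-based ``sensor_index``."""
        return self.pressure[:, sensor_index - 1]

    def shifted(self, dt: float) -> "PressureRecording":
        """Recording with the time origin moved by ``dt`` seconds.

        The stored grid still starts at 0 (the dialect requires it);
        annotations and the start position move so that physical events
        keep their absolute location.
        """
        meta = replace(self.metadata)
        if meta.mode == "pullback" and meta.pullback_rate:
            meta = replace(meta, start_position=meta.start_position - meta.pullback_rate * dt)
        anns = [replace(a, time=a.time + dt) for a in self.annotations]
        return PressureRecording(meta, self.time.copy(), self.pressure.copy(), anns)


def validate_recording(rec: PressureRecording) -> list[str]:
    """Check every dialect invariant; return human-readable findings.

    Returns the empty list iff the recording is valid. Never raises on a
    structurally well-formed object.
    """
    findings: list[str] = []
    m = rec.metadata
    if m.phase not in _PHASES:
        findings.append(f"phase: unknown value {m.phase!r}")
    if m.mode not in _MODES:
        findings.append(f"mode: unknown value {m.mode!r}")
    if m.units not in _UNITS:
        findings.append(f"units: unsupported unit {m.units!r}")
    if not (m.sampling_rate > 0):
        findings.append(f"sampling_rate: must be > 0, got {m.sampling_rate}")
    if m.sensor_count < 1:
        findings.append(f"sensor_count: must be >= 1, got {m.sensor_count}")
    if m.sensor_count > 1 and not (m.sensor_spacing > 0):
        findings.append(f"sensor_spacing: must be > 0 for multi-sensor, got {m.sensor_spacing}")
    if m.mode == "pullback":
        if m.pullback_rate is None or not (m.pullback_rate > 0):
            findings.append(f"pullback_rate: must be > 0 in pullback mode, got {m.pullback_rate}")
    elif m.pullback_rate is not None:
        findings.append("pullback_rate: must be absent in static mode")

    t = np.asarray(rec.time, dtype=float)
    p = np.asarray(rec.pressure, dtype=float)
    if p.ndim != 2 or p.shape[1] != m.sensor_count:
        findings.append(
            f"pressure: expected {m.sensor_count} channels, got shape {p.shape}"
        )
    if p.ndim == 2 and p.shape[0] != t.shape[0]:
        findings.append("pressure: channel length differs from time length")
    if len(t):
        if abs(t[0]) > _TIME_TOL:
            findings.append(f"time: must start at 0, got {t[0]}")
        if len(t) > 1 and m.sampling_rate > 0:
            step = 1.0 / m.sampling_rate
            if np.max(np.abs(np.diff(t) - step)) > _TIME_TOL:
                findings.append("time: grid not uniform at 1/sampling_rate")
    for a in rec.annotations:
        if a.resolution < 0:
            findings.append(f"annotation {a.label!r}: resolution must be >= 0")
        if len(t) and not (t[0] - a.resolution <= a.time <= t[-1] + a.resolution):
            findings.append(f"annotation {a.label!r}: time {a.time} outside recording span")
    return findings


def _paths(path: str | Path) -> tuple[Path, Path, Path]:
    stem = Path(path)
    if stem.suffix == ".csv":
        stem = stem.with_suffix("")
    return (
        stem.with_suffix(".csv"),
        Path(str(stem) + ".meta.json"),
        Path(str(stem) + ".events.csv"),
    )


def write_recording(rec: PressureRecording, path: str | Path) -> Path:
    """Write ``rec`` under stem ``path``; returns the data-table path.

    Value-exact round trip (17 significant digits).
    """
    data_path, meta_path, events_path = _paths(path)
    m = rec.metadata
    meta = {
        "subject_id": m.subject_id,
        "phase": m.phase,
        "mode": m.mode,
        "sampling_rate": m.sampling_rate,
        "sensor_count": m.sensor_count,
        "sensor_spacing": m.sensor_spacing,
        "start_position": m.start_position,
        "units": m.units,
    }
    if m.mode == "pullback":
        meta["pullback_rate"] = m.pullback_rate
    meta_path.write_text(json.dumps(meta, indent=1) + "\n")

    cols = {"time": np.asarray(rec.time, dtype=float)}
    for i in range(m.sensor_count):
        cols[f"p{i + 1}"] = np.asarray(rec.pressure[:, i], dtype=float)
    pd.DataFrame(cols).to_csv(data_path, index=False, float_format="%.17g")

    ev = pd.DataFrame(
        [(a.label, a.time, a.resolution) for a in rec.annotations],
        columns=["label", "time", "resolution"],
    )
    ev.to_csv(events_path, index=False, float_format="%.17g")
    return data_path


def read_recording(path: str | Path) -> PressureRecording:
    """Read and validate the recording stored under stem ``path``."""
    data_path, meta_path, events_path = _paths(path)
    if not data_path.exists():
        raise FileNotFoundError(data_path)
    if not meta_path.exists():
        raise RecordingFormatError(f"missing sidecar metadata {meta_path}")
    raw = json.loads(meta_path.read_text())
    if raw.get("units") not in _UNITS:
        raise RecordingFormatError(f"unknown units {raw.get('units')!r}")
    meta = RecordingMetadata(
        subject_id=str(raw["subject_id"]),
        phase=raw["phase"],
        mode=raw["mode"],
        sampling_rate=float(raw["sampling_rate"]),
        sensor_count=int(raw["sensor_count"]),
        sensor_spacing=float(raw["sensor_spacing"]),
        start_position=float(raw["start_position"]),
        pullback_rate=(float(raw["pullback_rate"]) if "pullback_rate" in raw else None),
    )
    table = pd.read_csv(data_path, float_precision="round_trip")
    expected = ["time"] + [f"p{i + 1}" for i in range(meta.sensor_count)]
    if list(table.columns) != expected:
        raise RecordingFormatError(
            f"channel columns {list(table.columns)} do not match sensor_count={meta.sensor_count}"
        )
    if table.isna().any().any():
        raise RecordingFormatError("missing values / odd-length channel in data table")
    time = table["time"].to_numpy(dtype=float)
    if len(time) > 1:
        step = 1.0 / meta.sampling_rate
        if np.max(np.abs(np.diff(time) - step)) > _TIME_TOL:
            raise RecordingFormatError("non-uniform time grid beyond 1e-6 s tolerance")
    pressure = table[expected[1:]].to_numpy(dtype=float)

    annotations: list[EventAnnotation] = []
    if events_path.exists():
        ev = pd.read_csv(events_path)
        for _, row in ev.iterrows():
            annotations.append(
                EventAnnotation(str(row["label"]), float(row["time"]), float(row["resolution"]))
            )
    rec = PressureRecording(meta, time, pressure, annotations)
    hard = [f for f in validate_recording(rec) if not f.startswith("annotation")]
    if hard:
        raise RecordingFormatError("; ".join(hard))
    return rec


def find_annotation(rec: PressureRecording, label: str = INJURY_CROSSING_LABEL) -> EventAnnotation | None:
    """First annotation with ``label``, or None."""
    for a in rec.annotations:
        if a.label == label:
            return a
    return None
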