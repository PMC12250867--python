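"""ROC/AUC and correlation analysis of proximal-vs-distal beat features.

After an aortic injury with vasospasm, pulse pressure measured proximal
to the injury tends to exceed the distal value, so per-beat features can
be scored for how well they separate proximal from distal waveforms.
Samples are labeled by sensor position relative to the injury, pooled
across subjects, and evaluated with a receiver operating characteristic
per feature (proximal = positive class); a single operating threshold is
chosen by Youden's J (max TPR − FPR). Features may first be normalized
by the per-recording maximum, which removes between-subject amplitude
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .beat_features import FEATURE_NAMES, detect_beats, extract_beat_features
from .waveform_io import PressureRecording

__all__ = [
    "ROCResult",
    "label_by_position",
    "labeled_samples_from_recording",
    "compute_roc_auc",
    "pearson_r",
    "evaluate_feature_set",
]

PROXIMAL, DISTAL = "proximal", "distal"


@dataclass
class ROCResult:
    feature_name: str
    normalized: bool
    points: np.ndarray  # (n, 2) array of (FPR, TPR), (0,0) .. (1,1)
    auc: float
    threshold: float  # Youden-optimal decision threshold


def label_by_position(sensor_positions, injury_position: float) -> list[str | None]:
    """Proximal/distal label per sensor position; None at the injury.

    Positions are centerline cm increasing distally: a sensor at a
    smaller coordinate than the injury is proximal. A sensor exactly at
    the injury position is excluded (labeled None).
    """
    labels: list[str | None] = []
    for x in sensor_positions:
        if x < injury_position:
            labels.append(PROXIMAL)
        elif x > injury_position:
            labels.append(DISTAL)
        else:
            labels.append(None)
    return labels


def labeled_samples_from_recording(
    rec: PressureRecording, injury_position: float
) -> pd.DataFrame:
    """Per-beat labeled feature samples from one static recording.

    Returns a tidy frame (subject_id, sensor_index, feature_name, value,
    label) with one row per beat per feature, labels from sensor
    position relative to the injury.
    """
    if rec.metadata.mode != "static":
        raise ValueError("position labeling requires a static recording")
    m = rec.metadata
    positions = [m.start_position + i * m.sensor_spacing for i in range(m.sensor_count)]
    labels = label_by_position(positions, injury_position)
    rows = []
    for i, label in enumerate(labels, start=1):
        if label is None:
            continue
        sig = rec.channel(i)
        beats = extract_beat_features(
            sig, detect_beats(sig, m.sampling_rate), m.sampling_rate, sensor_index=i
        )
        for b in beats:
            for name, value in (
                ("PPI", b.ppi),
                ("SBP", b.sbp),
                ("DBP", b.dbp),
                ("PP", b.pp),
                ("MAP", b.map),
            ):
                if np.isnan(value):
                    continue
                rows.append((m.subject_id, i, name, value, label))
    return pd.DataFrame(
        rows, columns=["subject_id", "sensor_index", "feature_name", "value", "label"]
    )


def compute_roc_auc(
    values, labels, feature_name: str = "", normalized: bool = False
) -> ROCResult:
    """ROC curve and AUC with proximal as the positive class.

    The trapezoidal AUC over all distinct thresholds equals the
    Mann-Whitney rank statistic: the probability that a random proximal
    value exceeds a random distal one, ties counting one half.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray([1 if l == PROXIMAL else 0 for l in labels])
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    fpr, tpr, thr = roc_curve(y, values, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    j = int(np.argmax(tpr - fpr))
    return ROCResult(
        feature_name=feature_name,
        normalized=normalized,
        points=np.column_stack([fpr, tpr]),
        auc=auc,
        threshold=float(thr[j]),
    )


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation and its two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need paired samples of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def evaluate_feature_set(
    manifest: list[tuple[PressureRecording, float]],
    features=FEATURE_NAMES,
    normalized: bool = False,
) -> pd.DataFrame:
    """One pooled ROC per feature over a cohort of static recordings.

    ``manifest`` pairs each recording with its injury centerline
    position. With ``normalized`` the values are first divided by the
    per-recording maximum of that feature (pooled over the recording's
    sensors), which preserves the within-recording proximal/distal
    contrast while removing between-recording scale.

    Returns a frame (feature, normalized, auc, threshold, n_proximal,
    n_distal) sorted by AUC descending.
    """
    frames = []
    for rec_id, (rec, injury_position) in enumerate(manifest):
        df = labeled_samples_from_recording(rec, injury_position)
        df["recording"] = rec_id
        frames.append(df)
    pooled = pd.concat(frames, ignore_index=True)
    if normalized:
        pooled["value"] = pooled["value"] / pooled.groupby(["recording", "feature_name"])[
            "value"
        ].transform("max")

    rows = []
    for name in features:
        sub = pooled[pooled.feature_name == name]
        roc = compute_roc_auc(sub["value"], sub["label"], name, normalized)
        rows.append(
            {
                "feature": name,
                "normalized": normalized,
                "auc": roc.auc,
                "threshold": roc.threshold,
                "n_proximal": int((sub.label == PROXIMAL).sum()),
                "n_distal": int((sub.label == DISTAL).sum()),
            }
        )
    return pd.DataFrame(rows).sort_values("auc", ascending=False, ignore_index=True)
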