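"""Change-point detection, sensor fusion, classification, full pipeline."""

from dataclasses import replace

import numpy as np
import pytest

from hemoloc.beat_features import moving_average
from hemoloc.localization import (
    LocalizeParams,
    PullbackTrack,
    SensorLayout,
    changepoint_time,
    classify_pullback,
    fuse_estimates,
    localize,
)
from hemoloc.waveform_io import find_annotation

from conftest import make_recording, pulse_train


# ------------------------------------------------------------- change-point

def test_changepoint_of_smoothed_step_is_at_step_center():
    t = np.arange(0, 30, 0.25)
    raw = np.where(t < 15.0, 45.0, np.where(t > 15.0, 40.0, 42.5))
    sm = moving_average(raw, 6)
    assert changepoint_time(t, sm) == pytest.approx(15.0)


def test_monotone_increasing_series_has_no_changepoint():
    t = np.arange(0, 10, 0.25)
    assert changepoint_time(t, 40 + 0.5 * t) is None


def test_changepoint_matches_exhaustive_derivative_scan():
    rng = np.random.default_rng(13)
    t = np.arange(0, 30, 0.25)
    sigmoid = 45 - 5 / (1 + np.exp(-(t - 17.3)))
    v = moving_average(sigmoid + rng.normal(0, 0.3, len(t)), 6)
    got = changepoint_time(t, v)
    derivs = [(v[i + 1] - v[i - 1]) / 2 for i in range(1, len(v) - 1)]
    oracle = t[1 + int(np.argmin(derivs))]
    assert got == oracle


def test_changepoint_tie_breaks_deterministically():
    # constant-slope descent: one long minimal plateau, resolved to its center
    t = np.arange(6, dtype=float)
    v = np.array([5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
    assert changepoint_time(t, v) == t[2]
    # two separated singleton minima: earliest wins
    t2 = np.arange(6, dtype=float)
    v2 = np.array([4.0, 4.0, 2.0, 4.0, 0.0, 4.0])
    assert changepoint_time(t2, v2) == t2[1]


def test_changepoint_needs_three_points():
    with pytest.raises(ValueError):
        changepoint_time(np.array([0.0, 1.0]), np.array([1.0, 0.0]))


# ------------------------------------------------------------------ fusion

DEFAULT_TRACK = PullbackTrack(rate=1.0, start_position=5.5)


def test_symmetric_layout_fusion_equals_plain_mean():
    t0 = 12.5
    times = {1: t0 + 7.5, 2: t0 + 2.5, 3: t0 - 2.5, 4: t0 - 7.5}
    fused_t, fused_x = fuse_estimates(times, SensorLayout(), DEFAULT_TRACK)
    assert fused_t == pytest.approx(t0)
    assert fused_t == pytest.approx(np.mean(list(times.values())))
    assert fused_x == pytest.approx(5.5 + t0)


def test_single_sensor_offset_correction():
    fused_t, _ = fuse_estimates({2: 15.0}, SensorLayout(), DEFAULT_TRACK)
    assert fused_t == pytest.approx(15.0 - 2.5)


def test_three_sensor_fusion_matches_hand_computed_mean():
    layout = SensorLayout(offsets=(6.0, 1.0, -3.0, -8.0))
    track = PullbackTrack(rate=2.0, start_position=0.0)
    times = {1: 10.0, 3: 9.0, 4: 12.0}
    fused_t, fused_x = fuse_estimates(times, layout, track)
    expected = np.mean([10.0 - 6.0 / 2, 9.0 + 3.0 / 2, 12.0 + 8.0 / 2])
    assert fused_t == pytest.approx(expected)
    assert fused_x == pytest.approx(2.0 * expected)


def test_fusion_requires_estimates():
    with pytest.raises(ValueError):
        fuse_estimates({}, SensorLayout(), DEFAULT_TRACK)


def test_fusion_is_unbiased_under_symmetric_errors():
    """Monte Carlo: symmetric per-sensor timing errors fuse to zero bias."""
    rng = np.random.default_rng(21)
    layout, track = SensorLayout(), DEFAULT_TRACK
    t0 = 12.5
    errors = []
    for _ in range(2000):
        eps = rng.normal(0, 1.0, 4)
        times = {i + 1: t0 + layout.offsets[i] / track.rate + eps[i] for i in range(4)}
        fused_t, _ = fuse_estimates(times, layout, track)
        errors.append(fused_t - t0)
    assert abs(np.mean(errors)) < 3 * np.std(errors) / np.sqrt(len(errors)) + 1e-3


# ------------------------------------------------------------ classification

def _series_with_slope(slope, n=100, step=0.25):
    from hemoloc.beat_features import Beat, resample_feature_series

    times = np.arange(n) * 1.0
    pp = 40 + slope * times
    beats = [
        Beat(1, t, t - 0.2, 80 + v, 80.0, v, 80 + v / 2, 1.0)
        for t, v in zip(times, pp)
    ]
    return resample_feature_series(beats, step)


def test_rising_pp_classified_baseline():
    cls, flags = classify_pullback([_series_with_slope(0.1)], map_mean=90.0)
    assert cls == "baseline" and not flags


def test_falling_pp_classified_injury():
    cls, flags = classify_pullback([_series_with_slope(-0.1)], map_mean=60.0)
    assert cls == "injury" and not flags


def test_low_map_overrides_slope():
    cls, flags = classify_pullback([_series_with_slope(-0.1)], map_mean=15.0)
    assert cls == "indeterminate"
    assert "LOW_MAP" in flags


def test_flat_pp_within_deadband_is_indeterminate():
    cls, _ = classify_pullback([_series_with_slope(0.0)], map_mean=90.0)
    assert cls == "indeterminate"


# ---------------------------------------------------------------- pipeline

def _toy_pullback(crossing_ref_time=12.5, rate=1.0, duration=26.0, drop=6.0):
    """4-channel pulse train whose PP steps down at each sensor's
    crossing time (reference crossing at ``crossing_ref_time``)."""
    fs = 500.0
    layout = SensorLayout()
    n = int(duration * fs)
    t = np.arange(n) / fs
    channels = []
    for i, off in enumerate(layout.offsets):
        t_cross = crossing_ref_time + off / rate
        pp = np.where(t < t_cross, 45.0, 45.0 - drop)
        channels.append(pulse_train(duration, fs=fs, hr_bpm=75, sbp=80 + pp, dbp=80.0, phase=0.05 * i))
    from hemoloc.waveform_io import EventAnnotation

    return make_recording(
        np.column_stack(channels),
        fs=fs,
        rate=rate,
        start_position=5.5 - layout.offsets[0],
        annotations=[EventAnnotation("midpoint_crossed_injury", crossing_ref_time, 0.0)],
    )


def test_localize_recovers_step_crossing():
    rec = _toy_pullback()
    res = localize(rec)
    assert res.classification == "injury"
    assert res.time_error == pytest.approx(0.0, abs=0.5)
    assert res.position_error == pytest.approx(0.0, abs=0.5)


def test_localize_translation_equivariance():
    r1 = localize(_toy_pullback(crossing_ref_time=11.0))
    r2 = localize(_toy_pullback(crossing_ref_time=14.0))
    assert r2.fused_time - r1.fused_time == pytest.approx(3.0, abs=0.3)


def test_localize_requires_pullback_mode():
    p = np.column_stack([pulse_train(4.0) for _ in range(4)])
    rec = make_recording(p, mode="static", rate=None)
    with pytest.raises(ValueError, match="pullback"):
        localize(rec)


def test_localize_on_noiseless_simulated_pullback(noiseless_injury_rec):
    """End-to-end: noiseless simulator recording localizes the true
    injury within grid step + truth quantization."""
    res = localize(noiseless_injury_rec)
    ann = find_annotation(noiseless_injury_rec)
    assert res.classification == "injury"
    assert abs(res.fused_time - ann.time) <= 0.25 + ann.resolution


def test_localize_baseline_simulated_pullback(baseline_rec):
    res = localize(baseline_rec)
    assert res.classification == "baseline"


def test_pullback_rate_scale_consistency(injury_sc):
    """Doubling the pullback rate leaves the position error (cm) of the
    noiseless pipeline comparable, while halving crossing-time spreads."""
    from hemoloc.experiments import generate_pullback
    from hemoloc.hemosim import NoiseSpec

    res1 = localize(generate_pullback(replace(injury_sc, noise=NoiseSpec.none()), seed=5))
    fast = replace(
        injury_sc,
        noise=NoiseSpec.none(),
        track=PullbackTrack(rate=2.0, start_position=5.5),
        duration=14.0,
    )
    res2 = localize(generate_pullback(fast, seed=5))
    spread1 = np.ptp([t for t in res1.per_sensor_time.values() if t is not None])
    spread2 = np.ptp([t for t in res2.per_sensor_time.values() if t is not None])
    assert spread2 == pytest.approx(spread1 / 2, abs=1.0)
    assert abs(res2.position_error) < 2.0
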