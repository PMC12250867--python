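"""Shared fixtures: toy waveform builders and session-scoped simulations."""

from __future__ import annotations

import numpy as np
import pytest

from hemoloc.experiments import (
    baseline_scenario,
    generate_pullback,
    injury_scenario,
    low_map_scenario,
)
from hemoloc.hemosim import (
    InflowSpec,
    NoiseSpec,
    build_default_human_aorta,
    simulate_cycles,
)
from hemoloc.waveform_io import (
    EventAnnotation,
    PressureRecording,
    RecordingMetadata,
)


def pulse_train(
    duration: float,
    fs: float = 1000.0,
    hr_bpm: float = 60.0,
    sbp: float = 120.0,
    dbp: float = 80.0,
    phase: float = 0.0,
) -> np.ndarray:
    """Idealized periodic arterial pulse: half-sine systole over diastole.

    ``sbp``/``dbp`` may be scalars or arrays over samples (for slowly
    drifting amplitude).
    """
    t = np.arange(int(round(duration * fs))) / fs
    period = 60.0 / hr_bpm
    tau = (t + phase) % period
    t_ej = 0.35 * period
    shape = np.where(tau < t_ej, np.sin(np.pi * tau / t_ej), 0.0)
    return dbp + (np.asarray(sbp) - np.asarray(dbp)) * shape


def make_recording(
    pressure: np.ndarray,
    fs: float = 1000.0,
    mode: str = "pullback",
    rate: float | None = 1.0,
    spacing: float = 5.0,
    start_position: float = -2.0,
    phase: str = "injury",
    annotations: list[EventAnnotation] | None = None,
) -> PressureRecording:
    """Wrap a (n, k) pressure array into a valid recording."""
    n, k = pressure.shape
    meta = RecordingMetadata(
        subject_id="toy",
        phase=phase,
        mode=mode,
        sampling_rate=fs,
        sensor_count=k,
        sensor_spacing=spacing,
        start_position=start_position,
        pullback_rate=rate if mode == "pullback" else None,
    )
    return PressureRecording(meta, np.arange(n) / fs, pressure, annotations or [])


@pytest.fixture(scope="session")
def human_model():
    return build_default_human_aorta()


@pytest.fixture(scope="session")
def injury_sc():
    """Default 800 ml/min injury scenario with a calibrated leak."""
    return injury_scenario().calibrated()


@pytest.fixture(scope="session")
def baseline_sc():
    return baseline_scenario()


@pytest.fixture(scope="session")
def injury_sim(injury_sc):
    """Centerline fields of the calibrated 800 ml/min injury run."""
    return simulate_cycles(
        injury_sc.model,
        injury_sc.inflow,
        vasospasm=injury_sc.vasospasm,
        leak=injury_sc.leak,
        n_cycles=15,
    )


@pytest.fixture(scope="session")
def baseline_sim(human_model):
    return simulate_cycles(human_model, InflowSpec(), n_cycles=15)


@pytest.fixture(scope="session")
def noisy_injury_rec(injury_sc):
    return generate_pullback(injury_sc, seed=0)


@pytest.fixture(scope="session")
def noiseless_injury_rec(injury_sc):
    from dataclasses import replace

    sc = replace(injury_sc, noise=NoiseSpec.none())
    sc = replace(sc, inflow=replace(sc.inflow, hr_variability=0.0))
    return generate_pullback(sc, seed=0)


@pytest.fixture(scope="session")
def baseline_rec(baseline_sc):
    return generate_pullback(baseline_sc, seed=1)


@pytest.fixture(scope="session")
def low_map_rec(injury_sc):
    """Deep-shock pullback sharing the injury scenario's calibration."""
    from dataclasses import replace

    sc = low_map_scenario()
    sc = replace(sc, leak=replace(sc.leak, leak_resistance=injury_sc.leak.leak_resistance))
    return generate_pullback(sc, seed=2)
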