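"""Canned synthetic experiments: scenario presets and ensemble evaluation.

A *scenario* bundles the aorta model, inflow, lesion specs, pullback
kinematics and noise into one reproducible configuration. The presets
here define the default study conditions: an 800 ml/min hemorrhage with
the default vasospasm at 18 cm for injury pullbacks, the unlesioned
model for baseline pullbacks, and a near-exsanguinated variant for
low-MAP quality-gate checks. ``evaluate_ensemble`` runs the full
generate → localize loop and summarizes signed localization errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hemosim import (
    AortaModel,
    InflowSpec,
    LeakSpec,
    NoiseSpec,
    VasospasmSpec,
    build_default_human_aorta,
    calibrate_leak_resistance,
    synth_pullback_recording,
)
from .localization import LocalizeParams, PullbackTrack, SensorLayout, localize
from .waveform_io import PressureRecording

__all__ = [
    "Scenario",
    "injury_scenario",
    "baseline_scenario",
    "low_map_scenario",
    "generate_pullback",
    "evaluate_ensemble",
]

#: default pullback: reference point starts at 5.5 cm (catheter tip at
#: -2 cm, just distal of the left subclavian) and withdraws at 1 cm/s
DEFAULT_TRACK = PullbackTrack(rate=1.0, start_position=5.5)
DEFAULT_DURATION_S = 26.0


@dataclass
class Scenario:
    """One reproducible synthetic acquisition configuration."""

    name: str
    model: AortaModel = field(default_factory=build_default_human_aorta)
    inflow: InflowSpec = field(default_factory=InflowSpec)
    vasospasm: VasospasmSpec | None = None
    leak: LeakSpec | None = None
    track: PullbackTrack = field(default_factory=lambda: replace(DEFAULT_TRACK))
    layout: SensorLayout = field(default_factory=SensorLayout)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    duration: float = DEFAULT_DURATION_S
    #: inflow used when calibrating the leak orifice; defaults to the
    #: scenario inflow. The orifice resistance is a property of the hole,
    #: so deep-shock scenarios calibrate it at pre-collapse pressures.
    calibration_inflow: InflowSpec | None = None

    def calibrated(self) -> "Scenario":
        """Scenario with the leak resistance calibrated to its target rate."""
        if self.leak is None or self.leak.target_mean_flow <= 0:
            return self
        if self.leak.leak_resistance is not None:
            return self
        r = calibrate_leak_resistance(
            self.model, self.leak, self.calibration_inflow or self.inflow, self.vasospasm
        )
        return replace(self, leak=replace(self.leak, leak_resistance=r))


def injury_scenario(
    hemorrhage_rate: float = 800.0, injury_position: float = 18.0
) -> Scenario:
    """Hemorrhage + vasospasm pullback at the default injury site.

    The inflow starts 500 ml into the bleed, so the blood-volume
    controller is active and mean pressure declines slowly during the
    recording, as it does once hemorrhage is established.
    """
    return Scenario(
        name=f"injury_{hemorrhage_rate:g}mlmin",
        inflow=InflowSpec(initial_loss_ml=500.0),
        vasospasm=VasospasmSpec(center_position=injury_position),
        leak=LeakSpec(position=injury_position, target_mean_flow=hemorrhage_rate),
    )


def baseline_scenario() -> Scenario:
    """Uninjured pullback: no leak, no spasm, full blood volume."""
    return Scenario(name="baseline")


def low_map_scenario(initial_loss_ml: float = 1800.0) -> Scenario:
    """Deep hemorrhagic shock: MAP driven below the 20 mmHg gate."""
    sc = injury_scenario()
    return replace(
        sc,
        name="low_map",
        inflow=replace(sc.inflow, initial_loss_ml=initial_loss_ml),
        calibration_inflow=sc.inflow,
    )


def generate_pullback(scenario: Scenario, seed: int) -> PressureRecording:
    """One synthetic pullback recording for a (calibrated) scenario."""
    return synth_pullback_recording(
        scenario.model,
        scenario.track,
        scenario.layout,
        scenario.noise,
        seed=seed,
        inflow=scenario.inflow,
        vasospasm=scenario.vasospasm,
        leak=scenario.leak,
        duration=scenario.duration,
        subject_id=f"{scenario.name}_{seed}",
    )


def evaluate_ensemble(
    scenario: Scenario,
    n: int,
    seed: int,
    params: LocalizeParams | None = None,
) -> pd.DataFrame:
    """Generate ``n`` seeded pullbacks, localize each, tabulate results.

    Member seeds are drawn from ``seed`` via a generator, so the whole
    table is reproducible from (scenario, n, seed). Columns: seed,
    classification, map_mean, fused_time, fused_position, time_error (s),
    position_error (cm), low_map flag.
    """
    scenario = scenario.calibrated()
    member_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    rows = []
    for s in member_seeds:
        rec = generate_pullback(scenario, int(s))
        res = localize(rec, params)
        rows.append(
            {
                "seed": int(s),
                "classification": res.classification,
                "map_mean": res.map_mean,
                "fused_time": res.fused_time,
                "fused_position": res.fused_position,
                "time_error": res.time_error,
                "position_error": res.position_error,
                "low_map": "LOW_MAP" in res.flags,
            }
        )
    return pd.DataFrame(rows)


def summarize_errors(table: pd.DataFrame) -> dict:
    """Signed-error mean/SD (s and cm) and mean absolute position error."""
    err_t = table["time_error"].dropna()
    err_x = table["position_error"].dropna()
    return {
        "n": int(len(table)),
        "n_localized": int(len(err_x)),
        "time_error_mean_s": float(err_t.mean()),
        "time_error_sd_s": float(err_t.std(ddof=1)),
        "position_error_mean_cm": float(err_x.mean()),
        "position_error_sd_cm": float(err_x.std(ddof=1)),
        "mean_abs_position_error_cm": float(err_x.abs().mean()),
    }
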