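"""Network construction, conservation, calibration, lesion signatures,
synthetic recording contracts."""

from dataclasses import replace

import numpy as np
import pytest

from hemoloc.hemosim import (
    AortaModel,
    InflowSpec,
    LeakSpec,
    NoiseSpec,
    VasospasmSpec,
    build_default_human_aorta,
    build_porcine_aorta,
    calibrate_leak_resistance,
    centerline_profiles,
    simulate_cycles,
    synth_pullback_recording,
    synth_static_recording,
)
from hemoloc.localization import PullbackTrack, SensorLayout
from hemoloc.waveform_io import write_recording


def _at(result, x):
    return int(np.argmin(np.abs(result.positions - x)))


# ------------------------------------------------------------ construction

def test_default_network_shape(human_model):
    assert len(human_model.terminals) == 9
    positions = [t.position for t in human_model.terminals]
    assert positions == sorted(positions)
    assert human_model.x_start == pytest.approx(-10.0)
    assert human_model.x_end == pytest.approx(41.0)
    # abdominal branch take-offs cluster distal of the default injury site
    abdominal = [t for t in human_model.terminals if 20 < t.position < 35]
    assert len(abdominal) == 4


def test_model_serialization_round_trip(human_model, tmp_path):
    human_model.save(tmp_path / "model.json")
    back = AortaModel.load(tmp_path / "model.json")
    assert back == human_model


def test_porcine_variant_is_scaled():
    pig = build_porcine_aorta()
    human = build_default_human_aorta()
    assert pig.x_end < human.x_end
    assert pig.segments[0].d_prox < human.segments[0].d_prox
    assert len(pig.terminals) == len(human.terminals)


def test_segment_taper_enforced():
    from hemoloc.hemosim import SegmentSpec

    with pytest.raises(ValueError, match="taper"):
        SegmentSpec("bad", 5.0, 1.5, 2.0, 0.01)


# ------------------------------------------------------- baseline dynamics

def test_baseline_physiologic_pressures(baseline_sim):
    i = _at(baseline_sim, 0.0)
    p = baseline_sim.pressure[:, i]
    assert 80 < p.mean() < 105
    assert 100 < p.max() < 130
    assert 60 < p.min() < 85


def test_baseline_distal_pp_amplification(baseline_sim):
    """No lesion: PP grows moving distally down the descending aorta."""
    pp = baseline_sim.pp_profile
    x = baseline_sim.positions
    sel = (x >= 0) & (x <= 40)
    assert pp[_at(baseline_sim, 40)] > pp[_at(baseline_sim, 0)] + 5
    slope = np.polyfit(x[sel], pp[sel], 1)[0]
    assert slope > 0.2


def test_volume_conservation_within_one_percent(baseline_sim, injury_sim):
    for sim in (baseline_sim, injury_sim):
        b = sim.cycle_balance
        imbalance = (b.vol_in - b.vol_terminals - b.vol_leak - b.storage_change).abs()
        assert (imbalance / b.vol_in).max() < 0.01


def test_dt_cap_enforced(human_model):
    with pytest.raises(ValueError, match="dt"):
        simulate_cycles(human_model, dt=5e-3)


# ------------------------------------------------------------------- leak

def test_calibrated_leak_hits_target_within_two_percent(injury_sc, injury_sim):
    assert injury_sim.mean_leak_flow == pytest.approx(800.0, rel=0.02)


def test_zero_target_leak_is_disabled(human_model):
    res = simulate_cycles(human_model, leak=LeakSpec(target_mean_flow=0.0), n_cycles=10)
    assert res.mean_leak_flow == 0.0
    assert res.truth_injury_position is None
    with pytest.raises(ValueError):
        calibrate_leak_resistance(human_model, LeakSpec(target_mean_flow=0.0))


def test_leak_is_ohmic(injury_sc, injury_sim):
    """Mean flow equals mean driving pressure over resistance."""
    leak = injury_sc.leak
    i = _at(injury_sim, leak.position)
    driving = injury_sim.pressure[:, i].mean() - leak.external_pressure
    expected = driving / leak.leak_resistance * 60.0
    assert injury_sim.mean_leak_flow == pytest.approx(expected, rel=0.03)


def test_uncalibrated_leak_rejected(human_model):
    with pytest.raises(ValueError, match="calibrate"):
        simulate_cycles(human_model, leak=LeakSpec(target_mean_flow=100.0), n_cycles=10)


def test_map_strictly_decreasing_in_leak_rate(human_model, injury_sc, injury_sim):
    """Mean aortic pressure falls monotonically with hemorrhage rate."""
    inflow = injury_sc.inflow
    spasm = injury_sc.vasospasm
    maps = []
    for rate in (0.0, 50.0, 100.0, 200.0):
        if rate == 0:
            res = simulate_cycles(human_model, inflow, vasospasm=spasm, n_cycles=12)
        else:
            lk = LeakSpec(target_mean_flow=rate)
            r = calibrate_leak_resistance(human_model, lk, inflow, spasm)
            res = simulate_cycles(
                human_model, inflow, vasospasm=spasm,
                leak=replace(lk, leak_resistance=r), n_cycles=12,
            )
        maps.append(res.pressure.mean())
    maps.append(injury_sim.pressure.mean())  # 800 ml/min
    assert all(a > b for a, b in zip(maps, maps[1:]))


# --------------------------------------------------------- lesion signature

def test_injury_pp_drop_and_velocity_rise(injury_sim):
    pp, esv = injury_sim.pp_profile, injury_sim.esv_profile
    drop = pp[_at(injury_sim, 16.0)] - pp[_at(injury_sim, 20.0)]
    rise = esv[_at(injury_sim, 18.0)] - esv[_at(injury_sim, 16.0)]
    assert drop > 2.0
    assert rise > 20.0


def test_spasm_only_differs_from_leak_plus_spasm(human_model, injury_sc, injury_sim):
    """Vasospasm alone narrows flow but cannot sustain the MAP deficit."""
    spasm_only = simulate_cycles(
        human_model, injury_sc.inflow, vasospasm=injury_sc.vasospasm, n_cycles=12
    )
    assert spasm_only.pressure.mean() > injury_sim.pressure.mean() + 5
    # both show a velocity spike in the spasm, only the leak loses volume
    assert spasm_only.mean_leak_flow == 0.0
    drop_spasm = (
        spasm_only.pp_profile[_at(spasm_only, 16.0)]
        - spasm_only.pp_profile[_at(spasm_only, 20.0)]
    )
    drop_leak = (
        injury_sim.pp_profile[_at(injury_sim, 16.0)]
        - injury_sim.pp_profile[_at(injury_sim, 20.0)]
    )
    # the local drop exists in both; only the leak case carries the
    # systemic deficit, so the two signatures are distinguishable
    assert drop_spasm > 2.0 and drop_leak > 2.0
    assert abs(drop_leak - drop_spasm) > 0.2


def test_centerline_profiles_table(injury_sim):
    table = centerline_profiles(injury_sim)
    assert list(table.columns) == ["position", "PP", "ESV"]
    assert len(table) == len(injury_sim.positions)
    np.testing.assert_allclose(np.diff(table.position), 0.5)


def test_controller_drives_map_below_gate(injury_sc):
    """Deep cumulative loss collapses stroke volume and mean pressure."""
    shocked = replace(injury_sc.inflow, initial_loss_ml=1800.0)
    res = simulate_cycles(
        injury_sc.model, shocked, vasospasm=injury_sc.vasospasm,
        leak=injury_sc.leak, n_cycles=12,
    )
    assert res.pressure.mean() < 20.0
    assert res.sv_scale.max() < 0.3


# ------------------------------------------------------ synthetic recordings

def test_adjacent_sensor_crossings_differ_by_five_seconds(injury_sc):
    layout = SensorLayout()
    track = injury_sc.track
    crossings = [
        (injury_sc.leak.position - (track.start_position - off)) / track.rate
        for off in layout.offsets
    ]
    diffs = np.diff(sorted(crossings))
    np.testing.assert_allclose(diffs, 5.0)


def test_noiseless_static_recording_is_periodic(human_model):
    rec = synth_static_recording(
        human_model, reference_position=15.0,
        noise=NoiseSpec.none(), inflow=InflowSpec(hr_variability=0.0),
        duration=5.0,
    )
    fs = rec.metadata.sampling_rate
    period = int(round(60.0 / 72.0 * fs))
    p = rec.channel(2)
    lag = p[period:] - p[:-period]
    assert np.abs(lag).max() < 0.6  # within interpolation error of one sample


def test_pullback_recording_deterministic_given_seed(injury_sc, tmp_path):
    from hemoloc.experiments import generate_pullback

    r1 = generate_pullback(injury_sc, seed=123)
    r2 = generate_pullback(injury_sc, seed=123)
    np.testing.assert_array_equal(r1.pressure, r2.pressure)
    assert r1.annotations == r2.annotations
    write_recording(r1, tmp_path / "a")
    write_recording(r2, tmp_path / "b")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_pullback_annotation_quantized_to_one_second(noisy_injury_rec):
    ann = noisy_injury_rec.annotations[0]
    assert ann.resolution == 1.0
    assert ann.time == round(ann.time)
    assert ann.label == "midpoint_crossed_injury"


def test_sensor_exiting_domain_rejected(injury_sc):
    bad = replace(injury_sc, track=PullbackTrack(rate=1.0, start_position=30.0))
    with pytest.raises(ValueError, match="exit"):
        from hemoloc.experiments import generate_pullback

        generate_pullback(bad, seed=0)


def test_vasospasm_outside_domain_rejected(human_model):
    with pytest.raises(ValueError, match="contained"):
        simulate_cycles(
            human_model, vasospasm=VasospasmSpec(center_position=60.0), n_cycles=10
        )
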