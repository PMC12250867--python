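"""Reduced-order aortic hemodynamics with vasospasm and hemorrhage leak.

The aorta is modeled as a chain of short compartments (0.5 cm default)
along the centerline: each node carries a pressure state on a wall
compliance, each edge a flow state with Poiseuille resistance and blood
inertance derived from the local lumen area. Branch arteries
(brachiocephalic, left carotid, left subclavian, celiac, superior
mesenteric, two renals, two iliacs) drain through three-element
Windkessel terminals. The heart is a half-sine ejection inflow at the
ascending-aortic inlet.

Two lesions can be superimposed:

* a **vasospasm** — a short region of reduced lumen area and wall
  compliance. Besides the area-scaled viscous terms (R ∝ 1/r⁴,
  L ∝ 1/r²), the spasm carries a Young-Tsai-type convective/expansion
  loss ΔP = k·Q|Q|, which is what actually produces a measurable
  systolic (hence pulse-pressure) drop at aortic scale;
* a **leak** — an Ohmic orifice draining a node to external pressure,
  with its resistance calibrated so the cycle-averaged leak flow hits a
  prescribed hemorrhage rate (50–800 ml/min).

A blood-volume controller scales stroke volume down once cumulative
leak loss exceeds 10% of the blood volume, reproducing the progressive
MAP decline of an uncontrolled hemorrhage down to degenerate
MAP < 20 mmHg states.

The integrator is a semi-implicit (symplectic-Euler) update — flows
advanced on current pressures, pressures on the new flows — at a 0.5 ms
step, comfortably inside the CFL bound for the ~4.5-5.7 m/s pulse-wave
speeds the compliance profile implies.

Centerline coordinate: 0 at the subclavian-adjacent pullback start,
increasing distally; the ascending aorta and arch sit at negative
coordinates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .localization import PullbackTrack, SensorLayout
from .waveform_io import (
    INJURY_CROSSING_LABEL,
    EventAnnotation,
    PressureRecording,
    RecordingMetadata,
)

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "SegmentSpec",
    "BranchTerminal",
    "AortaModel",
    "VasospasmSpec",
    "LeakSpec",
    "InflowSpec",
    "NoiseSpec",
    "SimResult",
    "build_default_human_aorta",
    "build_porcine_aorta",
    "calibrate_leak_resistance",
    "simulate_cycles",
    "centerline_profiles",
    "synth_pullback_recording",
    "synth_static_recording",
]

MMHG = 1333.22  # dyn/cm^2 per mmHg
BLOOD_VISCOSITY = 0.04  # g/(cm s)
BLOOD_DENSITY = 1.06  # g/cm^3
# Convective/expansion loss coefficient of the spasm constriction, in the
# Young-Tsai form dP = Kt * rho/(2 A0^2) * (A0/As - 1)^2 * Q|Q|. Reported
# values span ~1.0-2.5 with stenosis geometry; 2.2 reproduces the
# in-vivo-scale trans-injury pulse-pressure drop for the default spasm.
SPASM_LOSS_KT = 2.2

DIVERGENCE_LIMIT_MMHG = 500.0


@dataclass
class SegmentSpec:
    """One tapered aortic segment.

    ``compliance_per_length`` is dA/dP in cm²/mmHg (equivalently
    ml/(mmHg·cm) of volume compliance per centerline cm).
    """

    name: str
    length: float  # cm
    d_prox: float  # cm
    d_dist: float  # cm
    compliance_per_length: float  # cm^2/mmHg

    def __post_init__(self):
        if self.length <= 0 or self.d_prox <= 0 or self.d_dist <= 0:
            raise ValueError(f"{self.name}: lengths and diameters must be > 0")
        if self.d_dist > self.d_prox + 1e-12:
            raise ValueError(f"{self.name}: aortic taper requires d_dist <= d_prox")


@dataclass
class BranchTerminal:
    """Three-element Windkessel at a branch take-off."""

    name: str
    position: float  # cm on the centerline
    z_char: float  # mmHg s/ml
    r_distal: float  # mmHg s/ml
    compliance: float  # ml/mmHg
    p_venous: float = 3.0  # mmHg


@dataclass
class VasospasmSpec:
    """Localized constriction: reduced lumen area and wall compliance."""

    center_position: float = 18.0  # cm
    length: float = 2.0  # cm
    area_reduction: float = 0.60  # fraction of area lost, in [0, 1)
    compliance_reduction: float = 0.50

    def __post_init__(self):
        if not 0 <= self.area_reduction < 1:
            raise ValueError("area_reduction must be in [0, 1)")


@dataclass
class LeakSpec:
    """Hemorrhage orifice draining a centerline node to the outside."""

    position: float = 18.0  # cm
    orifice_diameter: float = 0.36  # cm (punch-biopsy injury size)
    target_mean_flow: float = 800.0  # ml/min
    leak_resistance: float | None = None  # mmHg s/ml, calibrated
    external_pressure: float = 0.0  # mmHg

    def __post_init__(self):
        if self.target_mean_flow < 0:
            raise ValueError("target_mean_flow must be >= 0")


@dataclass
class InflowSpec:
    """Half-sine ejection inflow plus the blood-volume controller.

    Stroke volume scales linearly from 1 down to ``min_sv_scale`` as
    cumulative blood loss grows from 10% to 40% of ``blood_volume_ml``.
    ``hr_variability`` is the fractional SD of per-cycle period jitter
    (applied only when a random generator is supplied).
    """

    heart_rate: float = 72.0  # beats/min
    stroke_volume: float = 75.0  # ml
    ejection_fraction_of_cycle: float = 0.33
    hr_variability: float = 0.02
    blood_volume_ml: float = 5000.0
    initial_loss_ml: float = 0.0
    min_sv_scale: float = 0.1

    def __post_init__(self):
        if not 30 <= self.heart_rate <= 240:
            raise ValueError("heart_rate outside [30, 240] beats/min")
        if self.stroke_volume <= 0:
            raise ValueError("stroke_volume must be > 0")


@dataclass
class NoiseSpec:
    """Measurement-layer disturbances added to synthetic recordings."""

    sensor_noise_mmhg: float = 0.5  # additive white noise SD per sensor
    resp_freq_hz: float = 0.2  # respiratory modulation frequency
    resp_amp_mmhg: float = 2.0  # respiratory modulation amplitude

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls(0.0, 0.2, 0.0)


@dataclass
class AortaModel:
    """Segment chain + branch terminals, with (de)serialization."""

    segments: list[SegmentSpec]
    terminals: list[BranchTerminal]
    x_start: float  # centerline coordinate of the inlet (cm)

    @property
    def x_end(self) -> float:
        return self.x_start + sum(s.length for s in self.segments)

    @property
    def extent(self) -> tuple[float, float]:
        return (self.x_start, self.x_end)

    def diameter(self, x: np.ndarray) -> np.ndarray:
        """Lumen diameter (cm) by linear taper within each segment."""
        x = np.asarray(x, dtype=float)
        d = np.empty_like(x)
        lo = self.x_start
        for seg in self.segments:
            hi = lo + seg.length
            m = (x >= lo - 1e-9) & (x <= hi + 1e-9)
            frac = np.clip((x[m] - lo) / seg.length, 0, 1)
            d[m] = seg.d_prox + (seg.d_dist - seg.d_prox) * frac
            lo = hi
        return d

    def compliance_per_length(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = np.empty_like(x)
        lo = self.x_start
        for seg in self.segments:
            hi = lo + seg.length
            m = (x >= lo - 1e-9) & (x <= hi + 1e-9)
            c[m] = seg.compliance_per_length
            lo = hi
        return c

    def to_dict(self) -> dict:
        return {
            "x_start": self.x_start,
            "segments": [asdict(s) for s in self.segments],
            "terminals": [asdict(t) for t in self.terminals],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AortaModel":
        return cls(
            segments=[SegmentSpec(**s) for s in d["segments"]],
            terminals=[BranchTerminal(**t) for t in d["terminals"]],
            x_start=float(d["x_start"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "AortaModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_default_human_aorta() -> AortaModel:
    """Default human aortic network (~51 cm centerline, 9 terminals).

    Geometry and Windkessel parameters are chosen for a resting adult:
    cardiac output ~5.4 l/min, MAP ~90 mmHg, aortic pulse-wave speed
    4.5-5.7 m/s, with terminal resistances apportioned by typical
    regional flow fractions. The coordinate origin is the pullback
    start near the left subclavian artery.
    """
    segments = [
        SegmentSpec("ascending", 4.0, 2.70, 2.60, 0.030),
        SegmentSpec("arch", 6.0, 2.60, 2.40, 0.022),
        SegmentSpec("thoracic", 20.0, 2.40, 2.20, 0.013),
        SegmentSpec("abdominal", 21.0, 2.20, 1.50, 0.0065),
    ]
    # (name, position cm, fraction of cardiac output)
    branches = [
        ("brachiocephalic", -5.0, 0.11),
        ("left_carotid", -3.5, 0.07),
        ("left_subclavian", -1.5, 0.07),
        ("celiac", 24.0, 0.12),
        ("superior_mesenteric", 26.0, 0.12),
        ("renal_left", 28.0, 0.09),
        ("renal_right", 29.5, 0.09),
        ("iliac_left", 41.0, 0.165),
        ("iliac_right", 41.0, 0.165),
    ]
    r_total = 1.0  # mmHg s/ml, parallel total
    c_total = 0.9  # ml/mmHg across terminals
    terminals = []
    for name, pos, frac in branches:
        r = r_total / frac
        terminals.append(
            BranchTerminal(
                name=name,
                position=pos,
                z_char=0.06 * r,
                r_distal=0.94 * r,
                compliance=frac * c_total,
            )
        )
    return AortaModel(segments=segments, terminals=terminals, x_start=-10.0)


def build_porcine_aorta(scale: float = 0.85) -> AortaModel:
    """Porcine-scaled variant: same topology, shorter and narrower.

    ``scale`` multiplies lengths and diameters; terminal resistances are
    raised (smaller cardiac output) and compliances reduced in
    proportion.
    """
    human = build_default_human_aorta()
    segments = [
        SegmentSpec(
            s.name,
            s.length * scale,
            s.d_prox * scale,
            s.d_dist * scale,
            s.compliance_per_length * scale**2,
        )
        for s in human.segments
    ]
    terminals = [
        BranchTerminal(
            t.name,
            t.position * scale,
            t.z_char / scale**2,
            t.r_distal / scale**2,
            t.compliance * scale**2,
            t.p_venous,
        )
        for t in human.terminals
    ]
    return AortaModel(segments=segments, terminals=terminals, x_start=human.x_start * scale)


@dataclass
class SimResult:
    """Centerline fields and derived profiles from one simulation."""

    positions: np.ndarray  # (N,) cm
    areas: np.ndarray  # (N,) cm^2, spasm-adjusted
    time: np.ndarray  # (T,) s, retained window re-zeroed
    pressure: np.ndarray  # (T, N) mmHg
    velocity: np.ndarray  # (T, N) cm/s
    pp_profile: np.ndarray  # (N,) mmHg
    esv_profile: np.ndarray  # (N,) cm/s
    mean_leak_flow: float  # ml/min over retained cycles
    truth_injury_position: float | None
    cycle_balance: pd.DataFrame  # per retained cycle volume bookkeeping
    end_systole_times: np.ndarray  # s, retained, re-zeroed
    sv_scale: np.ndarray  # controller stroke-volume scale per retained cycle

    @property
    def map_mean(self) -> float:
        return float(np.mean(self.pressure))


@njit(cache=True)
def _run_chain(
    dt,
    qin,
    cycle_index,
    n_cycles,
    C_node,
    R_edge,
    L_edge,
    K_edge,
    term_idx,
    term_zc,
    term_rd,
    term_c,
    term_pv,
    leak_idx,
    leak_r,
    leak_pext,
    blood_volume,
    initial_loss,
    min_sv_scale,
    record_stride,
    p_init,
):  # pragma: no cover - numba kernel, exercised via simulate_cycles
    n_steps = qin.shape[0]
    N = C_node.shape[0]
    M = term_idx.shape[0]
    n_rec = (n_steps + record_stride - 1) // record_stride

    P = np.full(N, p_init)
    Q = np.zeros(N - 1)
    Pwk = np.full(M, p_init * 0.9)
    net = np.zeros(N)

    P_rec = np.empty((n_rec, N))
    Q_rec = np.empty((n_rec, N - 1))
    qleak_rec = np.empty(n_rec)

    vol_in = np.zeros(n_cycles)
    vol_term = np.zeros(n_cycles)
    vol_leak = np.zeros(n_cycles)
    storage = np.zeros(n_cycles + 1)
    sv_scale = np.ones(n_cycles)

    v_lost = initial_loss
    scale = 1.0
    current_cycle = -1
    rec_i = 0
    diverged = False

    for i in range(n_steps):
        ci = cycle_index[i]
        if ci != current_cycle:
            current_cycle = ci
            loss_frac = v_lost / blood_volume
            s = 1.0 - max(loss_frac - 0.1, 0.0) / 0.3
            scale = min(1.0, max(min_sv_scale, s))
            sv_scale[ci] = scale
            st = 0.0
            for j in range(N):
                st += C_node[j] * P[j]
            for m in range(M):
                st += term_c[m] * Pwk[m]
            storage[ci] = st

        qin_i = qin[i] * scale

        # flows on current pressures (explicit), nonlinear spasm loss k Q|Q|
        for e in range(N - 1):
            dp = P[e] - P[e + 1] - R_edge[e] * Q[e] - K_edge[e] * Q[e] * abs(Q[e])
            Q[e] += dt * dp / L_edge[e]

        # terminal Windkessels
        qterm_sum = 0.0
        for j in range(N):
            net[j] = 0.0
        for m in range(M):
            qt = (P[term_idx[m]] - Pwk[m]) / term_zc[m]
            Pwk[m] += dt * (qt - (Pwk[m] - term_pv[m]) / term_rd[m]) / term_c[m]
            net[term_idx[m]] -= qt
            qterm_sum += qt

        qleak = 0.0
        if leak_idx >= 0:
            qleak = (P[leak_idx] - leak_pext) / leak_r
            net[leak_idx] -= qleak
            v_lost += qleak * dt

        # pressures on the new flows (semi-implicit pairing)
        net[0] += qin_i - Q[0]
        for j in range(1, N - 1):
            net[j] += Q[j - 1] - Q[j]
        net[N - 1] += Q[N - 2]
        for j in range(N):
            P[j] += dt * net[j] / C_node[j]
            if abs(P[j]) > DIVERGENCE_LIMIT_MMHG:
                diverged = True

        vol_in[ci] += qin_i * dt
        vol_term[ci] += qterm_sum * dt
        vol_leak[ci] += qleak * dt

        if i % record_stride == 0:
            for j in range(N):
                P_rec[rec_i, j] = P[j]
            for e in range(N - 1):
                Q_rec[rec_i, e] = Q[e]
            qleak_rec[rec_i] = qleak
            rec_i += 1
        if diverged:
            break

    st = 0.0
    for j in range(N):
        st += C_node[j] * P[j]
    for m in range(M):
        st += term_c[m] * Pwk[m]
    storage[n_cycles] = st
    return P_rec, Q_rec, qleak_rec, vol_in, vol_term, vol_leak, storage, sv_scale, diverged


def _discretize(
    model: AortaModel, vasospasm: VasospasmSpec | None, dx: float
) -> dict:
    """Node/edge arrays of the compartment chain, spasm applied."""
    x = np.arange(model.x_start, model.x_end + dx / 2, dx)
    area = np.pi * (model.diameter(x) / 2.0) ** 2
    area0 = area.copy()
    c_per_len = model.compliance_per_length(x)

    spasm_nodes = np.zeros(len(x), dtype=bool)
    if vasospasm is not None:
        lo = vasospasm.center_position - vasospasm.length / 2
        hi = vasospasm.center_position + vasospasm.length / 2
        if not (model.x_start < lo and hi < model.x_end):
            raise ValueError("vasospasm not contained in the modeled aorta")
        spasm_nodes = (x >= lo - 1e-9) & (x <= hi + 1e-9)
        a = 1.0 - vasospasm.area_reduction
        area[spasm_nodes] *= a
        c_per_len[spasm_nodes] = c_per_len[spasm_nodes] * (1.0 - vasospasm.compliance_reduction)

    C_node = c_per_len * dx
    a_edge = 0.5 * (area[:-1] + area[1:])
    R_edge = 8 * np.pi * BLOOD_VISCOSITY / a_edge**2 * dx / MMHG
    L_edge = BLOOD_DENSITY * dx / a_edge / MMHG

    K_edge = np.zeros(len(x) - 1)
    if vasospasm is not None and vasospasm.area_reduction > 0:
        a = 1.0 - vasospasm.area_reduction
        mid = np.argmin(np.abs(x - vasospasm.center_position))
        a0 = float(area0[mid])
        k_total = (
            SPASM_LOSS_KT * BLOOD_DENSITY / (2 * a0**2) * (1.0 / a - 1.0) ** 2 / MMHG
        )
        spasm_edges = spasm_nodes[:-1] & spasm_nodes[1:]
        n_edges = max(1, int(spasm_edges.sum()))
        K_edge[spasm_edges] = k_total / n_edges

    term_idx = np.array(
        [int(np.argmin(np.abs(x - t.position))) for t in model.terminals], dtype=np.int64
    )
    return {
        "x": x,
        "area": area,
        "C_node": C_node,
        "R_edge": R_edge,
        "L_edge": L_edge,
        "K_edge": K_edge,
        "term_idx": term_idx,
        "term_zc": np.array([t.z_char for t in model.terminals]),
        "term_rd": np.array([t.r_distal for t in model.terminals]),
        "term_c": np.array([t.compliance for t in model.terminals]),
        "term_pv": np.array([t.p_venous for t in model.terminals]),
    }


def _inflow_waveform(
    inflow: InflowSpec, n_cycles: int, dt: float, rng: np.random.Generator | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-step base inflow (ml/s), cycle index, cycle starts, end-systole times.

    The controller's per-cycle amplitude scale is applied inside the
    integrator; here the waveform integrates to the base stroke volume
    each cycle. Period jitter is drawn per cycle when ``rng`` is given.
    """
    t0 = 60.0 / inflow.heart_rate
    periods = np.full(n_cycles, t0)
    if rng is not None and inflow.hr_variability > 0:
        periods *= 1.0 + inflow.hr_variability * rng.standard_normal(n_cycles)
        periods = np.clip(periods, 60.0 / 240.0, 60.0 / 30.0)
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    n_steps = int(np.ceil(starts[-1] / dt))
    t = np.arange(n_steps) * dt
    cycle_index = np.minimum(np.searchsorted(starts, t, side="right") - 1, n_cycles - 1)
    tau = t - starts[cycle_index]
    t_ej = periods[cycle_index] * inflow.ejection_fraction_of_cycle
    q_peak = np.pi * inflow.stroke_volume / (2.0 * t_ej)
    qin = np.where(tau < t_ej, q_peak * np.sin(np.pi * tau / t_ej), 0.0)
    end_systole = starts[:-1] + periods * inflow.ejection_fraction_of_cycle
    return qin, cycle_index.astype(np.int64), starts, end_systole


def simulate_cycles(
    model: AortaModel,
    inflow: InflowSpec | None = None,
    vasospasm: VasospasmSpec | None = None,
    leak: LeakSpec | None = None,
    n_cycles: int = 12,
    discard_cycles: int = 5,
    dt: float = 5e-4,
    dx: float = 0.5,
    record_rate: float = 1000.0,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
) -> SimResult:
    """Integrate the compartment chain and return centerline fields.

    The first ``discard_cycles`` cycles are a start-up transient and are
    dropped from every output; retained time is re-zeroed. If
    ``duration`` is given, enough cycles are run so the retained window
    covers at least that many seconds. ``rng`` drives heart-rate
    variability only; all other dynamics are deterministic.
    """
    inflow = inflow or InflowSpec()
    if dt > 2e-3:
        raise ValueError("dt must be <= 2 ms")
    if duration is not None:
        t_min_cycle = (60.0 / inflow.heart_rate) * (1 - 4 * max(inflow.hr_variability, 0))
        n_cycles = discard_cycles + int(np.ceil(duration / t_min_cycle)) + 2
    if n_cycles < 10:
        raise ValueError("need n_cycles >= 10 (first cycles are transient)")

    grid = _discretize(model, vasospasm, dx)
    x = grid["x"]

    leak_idx = -1
    leak_r = np.inf
    leak_pext = 0.0
    truth = None
    if leak is not None and leak.target_mean_flow > 0:
        if leak.leak_resistance is None:
            raise ValueError("leak_resistance not set; run calibrate_leak_resistance first")
        leak_idx = int(np.argmin(np.abs(x - leak.position)))
        leak_r = float(leak.leak_resistance)
        leak_pext = float(leak.external_pressure)
        truth = float(leak.position)

    record_stride = max(1, int(round(1.0 / (record_rate * dt))))
    qin, cycle_index, starts, end_systole = _inflow_waveform(inflow, n_cycles, dt, rng)

    out = _run_chain(
        dt,
        qin,
        cycle_index,
        n_cycles,
        grid["C_node"],
        grid["R_edge"],
        grid["L_edge"],
        grid["K_edge"],
        grid["term_idx"],
        grid["term_zc"],
        grid["term_rd"],
        grid["term_c"],
        grid["term_pv"],
        leak_idx,
        leak_r,
        leak_pext,
        inflow.blood_volume_ml,
        inflow.initial_loss_ml,
        inflow.min_sv_scale,
        record_stride,
        80.0,
    )
    P_rec, Q_rec, qleak_rec, vol_in, vol_term, vol_leak, storage, sv_scale, diverged = out
    if diverged:
        raise RuntimeError(
            f"simulation diverged (|P| > {DIVERGENCE_LIMIT_MMHG} mmHg); "
            f"reduce dt={dt} or soften stiff spasm parameters"
        )

    t_rec = np.arange(P_rec.shape[0]) * record_stride * dt
    t_start = starts[discard_cycles]
    keep = t_rec >= t_start - 1e-12
    time = t_rec[keep] - t_start
    pressure = P_rec[keep]
    q = Q_rec[keep]

    # node velocity from adjacent edge flows and the (spasm-adjusted) area
    area = grid["area"]
    q_node = np.empty_like(pressure)
    q_node[:, 0] = q[:, 0]
    q_node[:, -1] = q[:, -1]
    q_node[:, 1:-1] = 0.5 * (q[:, :-1] + q[:, 1:])
    velocity = q_node / area

    es_kept = end_systole[discard_cycles:] - t_start
    es_kept = es_kept[es_kept <= time[-1] + 1e-9]
    es_idx = np.clip(np.round(es_kept / (record_stride * dt)).astype(int), 0, len(time) - 1)

    balance = pd.DataFrame(
        {
            "vol_in": vol_in,
            "vol_terminals": vol_term,
            "vol_leak": vol_leak,
            "storage_change": np.diff(storage),
        }
    ).iloc[discard_cycles:]
    mean_leak = float(np.mean(qleak_rec[keep])) * 60.0

    return SimResult(
        positions=x,
        areas=area,
        time=time,
        pressure=pressure,
        velocity=velocity,
        pp_profile=pressure.max(axis=0) - pressure.min(axis=0),
        esv_profile=velocity[es_idx].mean(axis=0),
        mean_leak_flow=mean_leak,
        truth_injury_position=truth,
        cycle_balance=balance,
        end_systole_times=es_kept,
        sv_scale=sv_scale[discard_cycles:],
    )


def calibrate_leak_resistance(
    model: AortaModel,
    leak: LeakSpec,
    inflow: InflowSpec | None = None,
    vasospasm: VasospasmSpec | None = None,
    tol: float = 0.02,
    max_iter: int = 50,
    **sim_kwargs,
) -> float:
    """Leak resistance whose cycle-averaged flow hits the target rate.

    Secant iteration on short steady simulations (no heart-rate jitter)
    until the simulated mean leak flow is within ``tol`` (2%) of
    ``leak.target_mean_flow``.
    """
    if leak.target_mean_flow <= 0:
        raise ValueError("target_mean_flow must be > 0 to calibrate (0 disables the leak)")
    inflow = inflow or InflowSpec()
    calm = replace(inflow, hr_variability=0.0)
    target = leak.target_mean_flow

    def mean_flow(r: float) -> float:
        trial = replace(leak, leak_resistance=r)
        res = simulate_cycles(
            model, calm, vasospasm=vasospasm, leak=trial,
            n_cycles=10, discard_cycles=5, **sim_kwargs,
        )
        return res.mean_leak_flow

    # Below ~0.1 mmHg s/ml the leak node becomes numerically stiff at the
    # default step; a resistance that low also means the target exceeds
    # what the circulation can deliver.
    r_min = 0.1

    # Ohmic guess from a plausible MAP, then secant
    r0 = (90.0 - leak.external_pressure) / (target / 60.0)
    f0 = mean_flow(r0) - target
    if abs(f0) <= tol * target:
        return r0
    r1 = max(r0 * (f0 + target) / target, r_min)
    f1 = mean_flow(r1) - target
    for _ in range(max_iter):
        if abs(f1) <= tol * target:
            return r1
        if f1 == f0:
            break
        r0, r1, f0 = r1, r1 - f1 * (r1 - r0) / (f1 - f0), f1
        r1 = max(r1, r_min)
        f1 = mean_flow(r1) - target
        if r1 == r_min and f1 < -tol * target:
            raise RuntimeError(
                f"target {target} ml/min is not achievable: even at the minimum "
                f"leak resistance {r_min} the mean flow falls short by {-f1:.1f} ml/min"
            )
    raise RuntimeError(
        f"leak calibration did not converge in {max_iter} iterations; "
        f"last bracket R=({r0:.4g}, {r1:.4g}), flow error {f1:.3g} ml/min"
    )


def centerline_profiles(result: SimResult) -> pd.DataFrame:
    """Per-position pulse pressure and end-systolic velocity table."""
    return pd.DataFrame(
        {
            "position": result.positions,
            "PP": result.pp_profile,
            "ESV": result.esv_profile,
        }
    )


def _check_extent(model: AortaModel, xs: np.ndarray) -> None:
    lo, hi = model.extent
    if xs.min() < lo - 1e-9 or xs.max() > hi + 1e-9:
        raise ValueError(
            f"sensor positions [{xs.min():.1f}, {xs.max():.1f}] cm exit the modeled "
            f"aorta [{lo:.1f}, {hi:.1f}] cm"
        )


def _sample_field(result: SimResult, times: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Pressure at (time, position) pairs, bilinear on the sim grid."""
    dt_rec = result.time[1] - result.time[0]
    ti = np.clip(times / dt_rec, 0, len(result.time) - 1)
    i0 = np.floor(ti).astype(int)
    i1 = np.minimum(i0 + 1, len(result.time) - 1)
    wt = ti - i0
    dx = result.positions[1] - result.positions[0]
    xi = np.clip((xs - result.positions[0]) / dx, 0, len(result.positions) - 1)
    j0 = np.floor(xi).astype(int)
    j1 = np.minimum(j0 + 1, len(result.positions) - 1)
    wx = xi - j0
    p = result.pressure
    return (
        p[i0, j0] * (1 - wt) * (1 - wx)
        + p[i0, j1] * (1 - wt) * wx
        + p[i1, j0] * wt * (1 - wx)
        + p[i1, j1] * wt * wx
    )


def synth_pullback_recording(
    model: AortaModel,
    track: PullbackTrack,
    layout: SensorLayout | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    inflow: InflowSpec | None = None,
    vasospasm: VasospasmSpec | None = None,
    leak: LeakSpec | None = None,
    duration: float = 26.0,
    sampling_rate: float = 1000.0,
    subject_id: str = "sim",
    truth_resolution: float = 1.0,
    settle_cycles: int = 12,
) -> PressureRecording:
    """Synthetic multi-sensor pullback recording with ground truth.

    Simulates the centerline pressure field, samples it at each sensor's
    moving position at ``sampling_rate``, and adds respiratory
    modulation (common to all sensors) plus independent white sensor
    noise. When a leak is active, the true time the layout reference
    point crosses it is annotated, quantized to ``truth_resolution``
    seconds (1 s mimics a stopwatch truth record).

    Deterministic given ``seed``: the same seed reproduces the recording
    bit for bit.
    """
    layout = layout or SensorLayout()
    noise = noise or NoiseSpec()
    inflow = inflow or InflowSpec()
    rng = np.random.default_rng(seed)

    result = simulate_cycles(
        model, inflow, vasospasm=vasospasm, leak=leak,
        duration=duration, record_rate=sampling_rate, rng=rng,
        discard_cycles=settle_cycles,
    )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    ref = track.start_position + track.rate * t
    pressure = np.empty((n, len(layout.offsets)))
    for i, off in enumerate(layout.offsets):
        xs = ref - off
        _check_extent(model, xs)
        pressure[:, i] = _sample_field(result, t, xs)

    resp_phase = rng.uniform(0, 2 * np.pi)
    if noise.resp_amp_mmhg > 0:
        pressure += noise.resp_amp_mmhg * np.sin(
            2 * np.pi * noise.resp_freq_hz * t + resp_phase
        )[:, None]
    if noise.sensor_noise_mmhg > 0:
        pressure += rng.normal(0, noise.sensor_noise_mmhg, size=pressure.shape)

    annotations = []
    phase = "baseline"
    if leak is not None and leak.target_mean_flow > 0:
        phase = "injury"
        t_true = (leak.position - track.start_position) / track.rate
        if 0 <= t_true <= duration:
            quantized = (
                round(t_true / truth_resolution) * truth_resolution
                if truth_resolution > 0
                else t_true
            )
            annotations.append(
                EventAnnotation(INJURY_CROSSING_LABEL, quantized, truth_resolution)
            )

    spacing = (
        abs(layout.offsets[0] - layout.offsets[1]) if len(layout.offsets) > 1 else 0.0
    )
    meta = RecordingMetadata(
        subject_id=subject_id,
        phase=phase,
        mode="pullback",
        sampling_rate=sampling_rate,
        sensor_count=len(layout.offsets),
        sensor_spacing=spacing,
        start_position=track.start_position - layout.offsets[0],
        pullback_rate=track.rate,
    )
    return PressureRecording(meta, t, pressure, annotations)


def synth_static_recording(
    model: AortaModel,
    reference_position: float,
    layout: SensorLayout | None = None,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    inflow: InflowSpec | None = None,
    vasospasm: VasospasmSpec | None = None,
    leak: LeakSpec | None = None,
    duration: float = 20.0,
    sampling_rate: float = 1000.0,
    subject_id: str = "sim",
    settle_cycles: int = 12,
) -> PressureRecording:
    """Synthetic static (fixed-position) multi-sensor recording."""
    layout = layout or SensorLayout()
    noise = noise or NoiseSpec()
    inflow = inflow or InflowSpec()
    rng = np.random.default_rng(seed)

    result = simulate_cycles(
        model, inflow, vasospasm=vasospasm, leak=leak,
        duration=duration, record_rate=sampling_rate, rng=rng,
        discard_cycles=settle_cycles,
    )
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    pressure = np.empty((n, len(layout.offsets)))
    for i, off in enumerate(layout.offsets):
        xs = np.full(n, reference_position - off)
        _check_extent(model, xs)
        pressure[:, i] = _sample_field(result, t, xs)

    resp_phase = rng.uniform(0, 2 * np.pi)
    if noise.resp_amp_mmhg > 0:
        pressure += noise.resp_amp_mmhg * np.sin(
            2 * np.pi * noise.resp_freq_hz * t + resp_phase
        )[:, None]
    if noise.sensor_noise_mmhg > 0:
        pressure += rng.normal(0, noise.sensor_noise_mmhg, size=pressure.shape)

    spacing = (
        abs(layout.offsets[0] - layout.offsets[1]) if len(layout.offsets) > 1 else 0.0
    )
    meta = RecordingMetadata(
        subject_id=subject_id,
        phase="injury" if (leak is not None and leak.target_mean_flow > 0) else "baseline",
        mode="static",
        sampling_rate=sampling_rate,
        sensor_count=len(layout.offsets),
        sensor_spacing=spacing,
        start_position=reference_position - layout.offsets[0],
    )
    return PressureRecording(meta, t, pressure, [])
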