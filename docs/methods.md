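# Methods

This note documents the models, algorithms and default parameters in
`hemoloc`, the reasoning behind the genuinely open design choices, and
what the synthetic experiments do and do not demonstrate.

## Signal pipeline

**Pre-filter.** Each channel is smoothed with a zero-phase 25 ms moving
average before beat analysis. The arterial pulse band (< ~15 Hz) passes
essentially unchanged while white sensor noise on the systolic and
diastolic extrema is reduced ~5-fold; without it, beat-to-beat PP noise
is comparable to the derivative of the crossing transient and the
change-point detector degrades sharply.

**Beat detection.** Systolic peaks are local maxima above an adaptive
threshold — rolling median plus 0.4 × rolling inter-quartile range over
a 4 s window — with a 0.25 s refractory period (caps implied heart rate
at 240 beats/min). The threshold percentiles are computed on a ~100 Hz
decimated copy and interpolated back; the threshold is a slowly varying
envelope, so this loses nothing while keeping the detector cheap. An
adaptive (rather than fixed) threshold matters because mean pressure can
fall by tens of mmHg within a single hemorrhage recording. Signals with
peak-to-trough range under 1 mmHg are treated as pulseless and yield no
beats.

**Beat delimitation.** A beat spans onset to next onset, the onset
being the pressure minimum between consecutive peaks. SBP/DBP/MAP are
the window max/min/mean; PP = SBP − DBP; PPI is the peak-to-peak
interval (undefined for the first beat).

**Resampling and filtering.** Per-beat values are linearly interpolated
onto a uniform 0.25 s grid (no extrapolation past the first/last beat)
and smoothed with a zero-phase centered moving average, default 3.0 s
(~4 beats at rest). The window must suppress beat-to-beat and
respiratory variation yet preserve the ~5 s transient produced by a
2 cm lesion crossed at 1 cm/s by sensors 5 cm apart; 3 s sits in the
middle of that trade-off. Edges are handled by window truncation, so
constants pass through unchanged.

**Normalization.** `normalize_feature_series` divides each feature by
its recording-wide maximum for that sensor (maximum of the normalized
series is exactly 1; idempotent). For pooled ROC analysis the
normalization is instead per recording per feature *across* sensors:
per-sensor normalization would erase the between-sensor contrast that
the proximal/distal comparison measures, while the per-recording form
removes between-subject amplitude scale and preserves it.

## Localization

The change-point of a smoothed PP series is the grid time minimizing
the central first difference. A boxcar-filtered ideal step yields a
*plateau* of equally minimal differences spanning the filter width, so
exact ties resolve to the center of the earliest minimal plateau: this
places an ideal smoothed step exactly at its midpoint, is deterministic,
and coincides with "earliest tie" whenever the minima are separated. The
scan skips the half-filter-width at each end of the series, where the
truncated window (and the final, possibly clipped beat) would otherwise
manufacture spurious extremes.

Per-sensor times are corrected by −dᵢ/v (offset over pullback rate)
before averaging. For the symmetric default layout — offsets
(+7.5, +2.5, −2.5, −7.5) cm about the midpoint of sensors 2 and 3 —
the corrections cancel and the fusion equals the plain average of raw
timestamps; the explicit correction makes the estimator unbiased for
arbitrary, asymmetric layouts too.

Classification uses the median over sensors of the least-squares slope
of smoothed PP versus time with a ±0.01 mmHg/s dead-band: rising →
baseline, falling → injury, inside the band → indeterminate. The
dead-band keeps flat profiles from being classified by noise. A
recording-mean MAP below 20 mmHg forces `indeterminate` with a
`LOW_MAP` flag regardless of slope, because the proximal/distal PP
difference becomes negligible near circulatory collapse and any
change-point found there is untrustworthy.

## Reduced-order aortic model

The aorta is discretized at Δx = 0.5 cm into a compartment chain: node
pressures evolve on wall compliance C′Δx, edge flows on Poiseuille
resistance 8πμΔx/A² and inertance ρΔx/A (μ = 0.04 g/(cm·s),
ρ = 1.06 g/cm³). Nine branch arteries (brachiocephalic, left carotid,
left subclavian, celiac, superior mesenteric, two renal, two iliac)
drain through three-element Windkessels whose resistances are
apportioned by typical regional flow fractions against a 1.0 mmHg·s/ml
parallel total and 0.9 ml/mmHg summed terminal compliance; venous
pressure is 3 mmHg. The inflow is a half-sine ejection (default 72
beats/min, 75 ml stroke volume, ejection occupying 33% of the cycle).

Default geometry (ascending 2.70→2.60 cm over 4 cm, arch 2.60→2.40 over
6 cm, thoracic 2.40→2.20 over 20 cm, abdominal 2.20→1.50 over 21 cm,
with compliance per length 0.030/0.022/0.013/0.0065 cm²/mmHg) gives a
resting adult operating point: MAP ≈ 93 mmHg, SBP/DBP ≈ 115/74, pulse
wave speed 4.5–5.7 m/s, and — through the distally rising characteristic
impedance and terminal reflections — the physiological distal *pulse
pressure amplification* (~40 → ~57 mmHg along the sampled centerline)
that makes baseline pullbacks show rising PP.

**Vasospasm.** A 2 cm region centered on the injury loses 60% of its
lumen area and 50% of its wall compliance. Viscous terms scale with
area (R ∝ 1/r⁴, L ∝ 1/r²), but at aortic scale those are negligible
(~0.1 mmHg); the physically dominant effect is the convective/expansion
loss of a short constriction, modeled in Young–Tsai form
ΔP = Kt·ρ/(2A₀²)·(A₀/Aₛ − 1)²·Q|Q| distributed over the spasm edges.
Kt was set to 2.2 during model construction — inside the ~1.0–2.5 range
reported for blunt constrictions — so that the default lesion
reproduces an in-vivo-scale trans-injury PP drop (~5 mmHg at the
800 ml/min condition). Because systolic flow is much larger than
diastolic, this loss clips systole preferentially and appears as a
step *down* in PP just distal of the lesion, the signature the
localizer keys on; it simultaneously accelerates flow through the
narrowing (end-systolic velocity roughly 2.5× for a 60% area loss,
a ~55 cm/s rise at the spasm center).

**Leak.** The injury orifice (3.6 mm default) drains its node to
external pressure through a linear resistance. The resistance is not a
free parameter: `calibrate_leak_resistance` secant-iterates short
steady simulations until the cycle-averaged leak flow matches the
prescribed hemorrhage rate (50–800 ml/min) within 2%. A zero target
disables the leak. Resistances below 0.1 mmHg·s/ml are refused — they
are numerically stiff at the default step and indicate an unreachable
target (the circulation cannot supply the requested rate). For
deep-shock scenarios the orifice is calibrated at pre-collapse
pressures and *reused*, so leak flow sags Ohmically as pressure falls,
as a real hole would.

**Blood-volume controller.** Stroke volume scales from 1 down to 0.1
linearly as cumulative loss (initial deficit plus integrated leak flow)
grows from 10% to 40% of a 5 l blood volume, with the scale updated at
each cycle onset from the loss actually accumulated in the integrator.
This produces the progressive MAP decline of uncontrolled hemorrhage
and, with a large initial deficit (~1.8 l), the degenerate MAP < 20 mmHg
states used to exercise the quality gate. The default injury scenario
starts 500 ml into the bleed, so pressure drifts slowly downward during
a recording, as it does once hemorrhage is established.

**Integration.** Semi-implicit (symplectic-Euler) pairing — flows
advanced on current pressures, then pressures on the new flows — at
dt = 0.5 ms. The CFL-type stability bound for this chain is
dt < Δx/c ≈ 0.9 ms at the fastest default wave speed; 0.5 ms leaves a
~2× margin that also covers stiffened spasm segments (a 1 ms step is
marginal there, which is why the default is finer; steps above 2 ms are
refused). Any pressure beyond ±500 mmHg aborts with a diagnostic. The
first cycles are a start-up transient: profile analyses discard 5
cycles, while synthetic recordings settle 12 cycles (~10 s) because the
slow volume/Windkessel settling (~1.5 s time constant) otherwise leaves
a visible drift at the recording start that mimics a change-point.

**Observables.** PP(x) is max − min of nodal pressure over the retained
window; ESV(x) is nodal velocity (edge-flow average over the
spasm-adjusted area) at the instant ejection ends, averaged over
retained cycles — end-systole is unambiguous in the simulator because
the inflow waveform defines it. Per-cycle volume bookkeeping (inflow =
terminal outflow + leak + compliance storage change) closes to < 1%.

## Synthetic recordings

Sensors sample the simulated pressure field at their moving positions
(bilinear interpolation in space and time) at 1 kHz. Measurement-layer
effects: additive white sensor noise (σ = 0.5 mmHg per sensor,
independent), respiratory modulation (0.2 Hz, ±2 mmHg, common to all
sensors, random phase), and per-cycle heart-period jitter (2%
fractional SD). When a leak is active the true reference-point crossing
time is annotated, rounded to 1 s, mimicking a stopwatch truth record.
All randomness flows from one seed; the same seed reproduces a
recording bit for bit.

The default pullback starts the catheter tip 2 cm distal of the left
subclavian take-off and withdraws at 1 cm/s for 26 s, so the reference
point crosses the default 18 cm injury mid-recording and adjacent
sensors cross exactly 5 s apart.

What the generator does *not* emulate: reflected-wave morphology of
real porcine/human pulses (dicrotic notch and secondary waves),
baroreflex heart-rate compensation, catheter motion artifacts,
variable manual pullback rate, and vasospasm dynamics (the spasm is
static). Passing tests therefore show the pipeline is correct and
robust at realistic signal-to-noise ratios and drift, not that it is
validated on animal or human data.

## Evaluation machinery

ROC analysis pools per-beat labeled samples across subjects (proximal =
positive class, since post-injury proximal PP tends to exceed distal);
AUC is trapezoidal over all distinct thresholds and equals the
Mann–Whitney rank statistic with ties counted one half; the operating
threshold maximizes Youden's J (TPR − FPR), the natural single-number
choice when no cost ratio is specified. Sensors exactly at the injury
position are excluded from labeling. Pearson correlations report the
standard product-moment coefficient with its two-sided t-based p-value.

## Problem sizes

Default experiment sizes — a 100-pullback noisy ensemble for the
localization-error estimate, 20 + 20 pullbacks for the
classification-separation check, 12–15 cardiac cycles per profile
simulation — were chosen so the complete synthetic study runs on a
laptop-class single core in well under a minute each while leaving
Monte-Carlo standard errors far smaller than the effects measured.

## Known limitations

* The compartment chain is a 1-D reduced-order model: no secondary
  flow, no fluid–structure interaction, no 3-D stenosis jet; the
  Young–Tsai closure stands in for all of these at the lesion.
* The leak is linear in the trans-mural pressure difference; real
  orifice flow is closer to square-root at high Reynolds numbers.
* Branch take-offs perturb the PP/ESV profiles (visible bumps near the
  abdominal branches) and are a genuine confounder for profile-based
  localization, as they are in vivo.
* The classifier's slope dead-band (0.01 mmHg/s) and the MAP gate
  (20 mmHg) are fixed operating points, not fitted to data.
* Truth quantization (1 s) bounds achievable pullback accuracy below
  ~0.5 cm at 1 cm/s regardless of algorithm quality.
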