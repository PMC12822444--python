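# Methods

## Forward model: airflow → surface temperature → voltage

The device's fluid-contact end is treated as a single lumped thermal mass.
Forced convection from airflow of speed `v` and temperature `T_air` obeys
Newton cooling, `q = h A (T_air − T_upper)`, with the laminar flat-plate
average-Nusselt correlation `h = 0.664 (κ/L) Re^{1/2} Pr^{1/3}`,
`Re = ρ v L / μ`. Combining with `q = m c_p dT_upper/dt` gives the linear
first-order ODE `dT_upper/dt = f(v)(T_air − T_upper)`, `f = hA/(mc_p)`. For
constant flow this has the closed-form exponential relaxation; for
time-varying flow the integrator holds `v` and `T_air` piecewise-constant
over each sampling interval (left endpoint) and applies the *exact*
exponential update per interval. The scheme is unconditionally stable, is
exact for constant inputs on any grid (machine precision; the test bound is
1e-9 K), and conserves energy per step by construction because the update
is the analytic solution of the interval's balance.

Assumptions and deliberate limits:

- `v` is a non-negative scalar speed normal to the plate; the full fluid
  field (Navier–Stokes) is not solved.
- `v = 0` gives `f = 0`: the surface temperature holds. No natural
  convection or radiation floor is added — the model is forced-convection
  only, so a device left in still air retains its last temperature rather
  than relaxing to ambient.
- `T_lower` (skin side) is constant; skin-coupled dynamics are out of scope.
- Air properties default to dry air near 20 °C: κ = 0.0257 W/(m·K),
  ρ = 1.2 kg/m³, μ = 1.8e-5 Pa·s, Pr = 0.71, all overridable in config.
- Units are kelvin internally; Celsius is accepted at config/CLI boundaries
  (`*_C` keys) and converted on read.

The plate geometry (L = 1 cm, A = 1 cm², m = 1 g, c_p = 200 J/(kg·K)) is a
plausible placeholder for a mask-mounted module: the real device's contact
mass and couple count are not public, so absolute device voltages are not
reproducible and only per-couple quantities (α = α_p − α_n = 412.5 µV/K,
hence 12.375 mV per couple at ΔT = 30 K) are treated as checkable.

## 1-D thermoelectric leg solver

A single leg is solved in steady state on `x ∈ [0, L]`:
`d/dx(κ dT/dx) + ρ_el j² = 0`, `j` uniform (charge conservation in 1-D),
`j = −σ(dE/dx + α dT/dx)`, with Dirichlet `T(0) = T_lower` and a Robin
condition `κ T'(L) = h (T_air − T(L))` at the fluid-contact end. The Seebeck
coefficient is constant per material, so the Thomson term vanishes
identically — a modelling choice, not an omission. Side faces are adiabatic;
radiation is neglected; material properties are temperature-independent.

Discretization: second-order central differences with a ghost-node Robin
closure, assembled tridiagonally and solved with a banded LU
(`scipy.linalg.solve_banded`). Because the exact solution is linear (open
circuit) or quadratic (uniform Joule source), the scheme is nodally exact up
to round-off; the residual tolerance used in tests is 1e-9 K. Loaded
operation iterates a fixed point: current from the series circuit
(EMF α·ΔT over internal resistance `L/(σA)` plus `R_load`), then a re-solve
with the Joule source, until the relative current change is ≤ 1e-8
(typically < 10 iterations; non-convergence raises with diagnostics).

The couple sweep drives both legs open-circuit with `h(v)` from the
convection law (characteristic length = leg side length) and reports
`V_oc = α_p ΔT_p − α_n ΔT_n` and the mean leg ΔT. Only the monotone
velocity trend is asserted — the reference magnitudes exist only as figures.

## Synthetic physiology

The generators emulate the *structure* of the signals the recognition layer
needs, not their acoustics or fluid mechanics. All are pure functions of
(parameters, seed); seeds are split from a root seed with
`numpy.random.SeedSequence`.

- **Breathing**: half-sinusoid exhale lobes (airflow at 38 °C) alternating
  with weaker inhale lobes (ambient 20 °C), default 15 breaths/min, peak
  1.5 m/s — inside the measured normal-respiration envelope of 0.5–2.5 m/s,
  which the generator also enforces by clipping. Feeble respiration
  (breathing-resistor surrogate) reduces the peak to 0.3 m/s; weightless
  respiration (drop surrogate) blanks the flow for ~0.5 s mid-record and
  follows with a ~3.2 m/s recovery gasp.
- **Speech**: one sinusoidal airflow burst per spoken word, with per-burst
  onset jitter and Gaussian noise. The five classifier phrases differ in
  burst count, timing and amplitude. Distress shouts (HELP/Ah/Oy) carry
  peak airflow 3.0–3.5 m/s, above the calm-speech band (< 2 m/s): class
  separability is an explicit design obligation of the generator, and shout
  airflow exceeding conversational airflow is the physical rationale.
- **Coughs**: 0.25 s transients with peak speeds 3 / 4.5 / 6 m/s for
  mild / moderate / severe, jittered around evenly spaced slots with a
  0.5 s minimum spacing.
- **Heartbeat**: PPG-like sum of per-beat two-Gaussian pulses (systolic +
  dicrotic) at jittered beat times. Resting 60 bpm (interval CV 0.03),
  exercising 120 bpm (CV 0.04); the abnormal (pain-stimulus surrogate) kind
  uses 80 bpm with CV 0.25 plus a 3 s window in which beat amplitudes drop
  to 25%.
- **Fusion datasets** are balanced over the four (TED-state, heartbeat-state)
  combinations; abnormal TED sources are drawn from {distress speech,
  feeble, weightless}, normal ones from {calm speech, normal breathing};
  every airflow is run through the forward model so TED traces satisfy
  `V = α ΔT` pointwise, and the fused label is *abnormal* iff both channels
  are abnormal.

What passing tests on these signals show: that the physics chain, the
feature extraction and the decision layers behave correctly on data with
the right ranges, rates and class structure. What they do not show:
robustness to real-world variability (inter-subject differences, sensor
drift, motion artefacts, acoustic confounds), which no synthetic surrogate
of this kind can establish.

## Feature extraction and detection

**Spectral features** are Hann-windowed magnitude spectrograms (default
0.5 s frames, 0.25 s hop), log-transformed, cropped to ≤ 15 Hz (breathing,
pulse harmonics and burst transients all live well below that), and
bilinearly resampled to a fixed 12 × 16 (frames × frequencies) grid so every
recording yields the same feature length regardless of duration.

**Cough detection** operates on the high-passed voltage *rate*: a cough is
a fast strong convective transient, so the voltage steps up and holds,
making dV/dt (minus its 0.75 s moving average, which removes
breathing-scale variation) the discriminative signal. Intensity bands are
derived from the forward model — a cough of peak speed `v` drives the
surface at rate `≈ f(v)·(38 °C − T_lower)` — scaled by a once-calibrated
high-pass attenuation factor (0.74 at 100 Hz), with band edges midway
between the predicted mild/moderate/severe responses. Thresholds live in
config, not code. The **alarm rule** slides a closed 5 s window over
severe events only and activates at the event completing a count of three;
anchoring the window at events (rather than on a fixed grid) makes the rule
a pure function of the event times.

## Classifiers

**Speech**: a fully-connected feed-forward network (two hidden layers,
64/32 rectified units, softmax output; scikit-learn `MLPClassifier` behind a
`StandardScaler`) trained with the 9-train / 1-test split per class on
10 samples per class; the held-out sample per class is chosen by seed.
Reported accuracy is the mean over ≥ 20 seeds (each seed regenerates the
dataset and the split).

**Fusion**: gradient-boosted trees (XGBoost; depth 3, 200 rounds, learning
rate 0.1) on concatenated TED + heartbeat spectral vectors with a 25%
stratified hold-out. Column subsampling (0.3) and row subsampling (0.8) are
essential here, not cosmetic: the fused label is a conjunction
(abnormal = abnormal-TED ∧ abnormal-heartbeat), and without feature
subsampling the greedy ensemble over-commits to the single most separable
channel and plateaus well below ceiling; forcing trees to draw on both
feature blocks lets the ensemble represent the interaction. The surrogate
experiment uses 100 recordings per combination (400 total): conjunction
learning from generic spectral features is more sample-hungry than either
marginal task, and holdout accuracy saturates around this size. Dataset
sizes, like all generator parameters, are fixed defaults, and accuracies
are reported as means over ≥ 20 seeds. A label-shuffle null control is kept
in the tests: with the 1:3 class split, chance lies between
proportion-matching (0.625) and majority voting (0.75), and shuffled
training must fall into that band.

## Numerical choices and degenerate inputs

- Integrator: exact exponential per interval; no step-size restriction.
- Leg solver: tridiagonal banded solve; fixed-point tolerance 1e-8 on
  current, 200-iteration cap with a diagnostic error.
- Spectrogram: `log10(|X| + 1e-12)` guards all-zero traces; traces shorter
  than one frame, non-uniform sampling, and `frame_len ≤ hop` are rejected.
- Generators reject non-positive durations, sampling below 20 Hz, cough
  counts that cannot fit the window at minimum spacing, and out-of-range
  normal-breathing peaks.
- CSV readers fail with the offending row number for non-monotone time,
  missing columns, NaNs and empty files; configs reject unknown keys.

## Known limitations

- Absolute device outputs require the (unpublished) couple count and
  contact-end thermal mass; only per-couple quantities are checked.
- The convection law is a laminar flat-plate average; coughs at 6 m/s over
  a centimetre plate approach the correlation's comfort zone but remain
  laminar (Re ≈ 4000 ≪ 5·10⁵).
- The alarm's intensity bands are calibrated to the generator's cough
  peaks; a real deployment would calibrate them per device and wearer.
- Classifier accuracies quantify performance on the synthetic surrogate
  tasks only.
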