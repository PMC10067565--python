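# Methods

This note documents the models, numerical choices and open design decisions
behind `eitpose`, in the spirit of a model-description appendix. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The lung model

The thorax cross-section is an ellipse with anterior–posterior span
`thorax_ap_cm` (default 22 cm) and right–left span `thorax_rl_cm` (default
30 cm) — a chest is wider than deep, which is the geometric fact that makes
everything else work. Each pixel of the 32 × 32 EIT grid that falls inside
the two-ellipse lung mask holds one lung unit with body-fixed coordinates;
the electrode belt rotates with the animal, so pixel coordinates and ROI
masks never change with posture. Only the gravity axis rotates: supine
gravity points anterior→posterior, a 30° left-lateral tilt rotates it
toward the animal's left. The gravitational depth of a unit is its
projection on the gravity axis measured from the uppermost point of the
thorax ellipse, and pleural pressure is linear in that depth:

    P_pl = pleural_offset + pleural_gradient × depth
    P_L  = P_aw − P_pl

Defaults: `pleural_offset = −3 cmH2O` (slightly negative at the
non-dependent pleura), `pleural_gradient = 0.7 cmH2O/cm`. Neither quantity
is directly measurable in a ~69 kg pig without pleural sensors, so both are
configuration parameters; the defaults were chosen so that a supine lung at
PEEP 10 cmH2O carries an end-expiratory `P_L` near zero at the dorsal
boundary — the regime in which dependent collapse happens. Because the
right–left span exceeds the anterior–posterior span, the across-units range
of `P_L` is strictly wider in lateral than in supine posture for any
positive gradient (this is asserted as a property test by brute force over
all units).

## Recruitment and derecruitment

Each unit carries an opening and a closing pressure with
`opening ≥ closing` (hysteresis). Per breath:

- a closed unit **opens** when end-inspiratory `P_L = PEEP + ΔP − P_pl`
  exceeds its opening pressure;
- an open unit whose end-expiratory `P_L = PEEP − P_pl` falls below its
  closing pressure becomes *eligible* and **closes after a per-unit delay**
  of `collapse_delay_breaths/3 … collapse_delay_breaths` breaths (default
  13–40 breaths ≈ 26–80 s at 30/min); while the countdown runs, the unit's
  aeration declines linearly, and any ventilator change or return of
  support resets the countdown and restores the unit;
- otherwise the state persists.

Driving pressure is emergent, `ΔP = V_T / Σ compliance(open)`, so
recruitment lowers ΔP at fixed tidal volume and derecruitment raises it.
The progressive (rather than instantaneous) derecruitment serves two
purposes: it reproduces the minutes-scale EELI decline that the titration
criteria were designed to observe, and it gives a closed-loop controller
something to detect *before* a marginal unit is lost. With
`collapse_delay_breaths = 0` the textbook immediate rule applies (used in
the single-unit trajectory tests).

Injury interpolates the pressure thresholds between a healthy lung
(opening ≤ 0: nothing ever stays closed at PEEP ≥ 0) and a
surfactant-depleted one whose thresholds increase with anatomical
ventral→dorsal depth plus seeded noise. At full injury the defaults
(closing ≈ 3 + 0.05·depth, opening ≈ 21 + 0.42·depth cmH2O) put the
critical opening pressures of the dorsal units *above* the inspiratory
pressures reachable in supine (plateau ≈ 29–33 cmH2O) while their closing
pressures sit a few cmH2O above the initial PEEP. That large effective
hysteresis is deliberate and is the central mechanism of the sequential
strategy: dorsal units cannot be opened by supine PEEP increments alone,
they *can* be opened by the extra `P_L` a lateral posture gives the
non-dependent lung, and once open they stay open in supine provided PEEP
exceeds their (much lower) closing requirement — which is exactly the PEEP
the lateral titration finds. A narrow hysteresis (opening − closing of only
a few cmH2O) would contradict this regime, because supine plateau pressures
would re-open everything and the position sequence would add nothing.

The initial open/collapsed pattern is set by the opening rule at the peak
pressure of the preceding (injurious-ventilation) phase
(`initial_peak_pressure`, default 40 cmH2O in the protocol scenarios);
the settling breaths of the first supine step then bring the state to the
closing-rule steady state.

## Signal rendering

Per pixel and frame the rendered impedance is the sum of:

- an end-expiratory baseline ∝ compliance × max(frc_pressure + P_L_ee, 0)
  for open units (zero when collapsed) — EELI rises with PEEP and falls
  with derecruitment;
- a tidal component for open units, amplitude ∝ compliance × ΔP, shaped by
  a raised-cosine inspiration/expiration waveform honouring the I:E ratio
  (exact zero at end-expiration, exact peak at end-inspiration, so tidal
  amplitudes are analytically known);
- a cardiac oscillation ∝ the unit's perfusion fraction, at
  `cardiac_rate` = 83/min by default — deliberately *not* an integer
  multiple of the respiratory rate, since a phase-locked heart would alias
  into the breath-synchronous samples instead of averaging out;
- white Gaussian sensor noise (`noise_sd`, default 0.05 A.U. per pixel per
  frame);
- during apnea, after a bolus event: a negative deflection (saline lowers
  impedance) ∝ the unit's perfusion fraction, shaped by a gamma-variate
  first-pass kernel `(t/t_p)^α exp(α(1 − t/t_p))` with arrival delay 1 s,
  time-to-peak 2.5 s and shape α = 3 — the conventional indicator-dilution
  form.

Impedance is calibrated 1 A.U./mL (`z_per_ml`), so a 350 mL tidal volume
gives a global ΔZ of 350 A.U. Rendering freezes the recruitment state
within a segment; state dynamics happen in the coarse breath loop between
rendered segments, and protocol sequences render the end-of-step
measurement epochs back-to-back on a contiguous 50 Hz time axis.

## Perfusion model

Per-unit blood-flow weight = base × (1 + gravity_perfusion_slope × depth)
× vascular factor, renormalized to sum to 1. The vascular factor is
`hpv_factor` (default 0.6) for collapsed units — hypoxic pulmonary
vasoconstriction — and, for open units, a conductance linear in
end-expiratory `P_L` (slope 0.16/cmH2O around a 5 cmH2O reference). The
linear aeration term is a deliberate extension beyond a binary HPV factor:
with a collapsed-only factor, recruitment of the non-dependent dorsal
quadrant raises total weight and renormalization *forces the non-dependent
ventral share down*, whereas the experimentally observed pattern is a gain
in both non-dependent quadrants. A conductance that grows with local
distension shifts flow toward whichever lung moves up, reproducing the
non-gravitational redistribution, while the collapsed-unit factor still
couples perfusion to recruitment (shunt). The shunt fraction — summed
perfusion of collapsed units — feeds a logistic oxygenation surrogate
pinned to 500 mmHg at zero shunt and 40 mmHg at full shunt, steepest near
5 % shunt; it is a qualitative surrogate, not blood-gas physics.

## Ventilation analysis

Breaths are detected on the lung-summed global curve: a zero-phase
band-pass (0.3–2.5 × the ventilatory frequency) finds the end-expiratory
minima, then each breath is aligned by least squares to the
ensemble-average breath (matched template, two iterations) and the
template's own breath-averaged minimum fixes the absolute offset.
Filtering alone systematically shifts the extrema of an asymmetric breath
waveform, and a pointwise raw minimum is noise-limited because
end-expiration is flat; template alignment concentrates the whole breath
energy into the timing estimate. ΔZ and EELI amplitudes are read from the
*raw* pixel values at the refined indices, so filtering never biases
amplitudes. Regional ΔZ is additive by construction (sums of per-pixel
differences), ventilation shares are `100 × ΔZ_r / ΔZ_total` with negative
regional ΔZ clipped to zero (and logged) before normalization, and the
partition identities `Σ V_Tr = V_T`, `Σ C_Z = V_T/ΔP`, `C_Z × ΔP = V_Tr`
hold to machine precision. Per-step reporting uses the final rendered
epoch of each position, dropping one breath at each epoch edge against
filter edge effects. ΔEELI between epochs is a difference of epoch means of
end-expiratory values; a linear drift estimate is attached but not
subtracted.

## Perfusion analysis

Within the apnea window the per-pixel baseline is the pre-bolus apneic
mean; deflection = baseline − signal (sign-corrected positive); a
zero-phase low-pass at half the cardiac frequency suppresses the cardiac
oscillation without distorting the upslope. The default per-pixel metric is
the maximal upslope of the first-pass deflection; an area-under-curve
metric (integrated to the first post-peak local minimum of the summed
curve, to exclude recirculation) is available behind a switch, since
indicator-dilution practice uses both and the choice is not dictated by the
data. Negative pixel metrics are clipped to zero and logged; shares are
normalized to 1, making the distribution invariant to any positive
rescaling of the deflections. A contrast-free recording is rejected via a
significance floor relative to the baseline scale.

## PEEP titration

The engine consumes per-breath observations (time, global EELI,
dependent-lung EELI) and a ventilator callback, so the same loop drives the
simulator or a replayed recording. From an initial 10 cmH2O, PEEP rises in
2 cmH2O steps until, simultaneously: (a) global EELI has stopped
decreasing; (b) dependent-lung EELI has stopped decreasing sustained over a
2-minute window that restarts after every PEEP change (each new level must
earn its own stabilization evidence); (c) the cumulative dependent-lung
EELI drop since lateral onset is at most `dz_multiple` (default 1.0, the
permissive end of the 0.5–1.0 range; no per-animal value is claimed) times
the dependent lung's ΔZ from the preceding supine epoch.

"Stops decreasing" is operationalized as *both* a least-squares slope above
−0.2 %/min of the reference ΔZ *and* a window-maximum-to-current drop
below 0.2 % of the reference ΔZ. The slope test alone is blind to a
single-unit derecruitment landing at the edge of the evaluation window; the
drop detector catches it wherever it lands. The tolerances are expressed
relative to the reference ΔZ so they scale with signal calibration; they
are chosen for the noise-free simulator streams and should be widened for
noisy replayed recordings. A 15 s warm-up precedes the first slope
evaluation after each PEEP change, and a safety cap (`max_peep`, default
24 cmH2O) bounds an otherwise unbounded upward loop; hitting it is flagged
`max_peep_reached`.

For benchmarking, `scenarios.titration_scenario` constructs
derecruitment-only scenarios (opening pressures pushed out of reach) whose
correct answer is closed-form: the smallest `10 + 2k` at or above
`c = max(closing + P_pl,lateral)` over the open dependent units. The
titration engine meets this answer exactly provided detection is faster
than the fastest unit's collapse — which the delay floor (≈ 26 s)
guarantees against the 15 s evaluation warm-up. This closed-form equality
is a property of reactive EELI-criteria titration in general: the criteria
keep failing while any supported-at-onset unit remains below its closing
requirement, and pass one full window after the last one is covered.

## Protocol runner and statistics

The five steps run in fixed order; each step simulates 450 coarse breaths
(the 15-minute step at 30/min — steady state, not wall clock, is what
matters) before its measurement epoch (default 60 s of breathing, plus a
20 s apnea with a bolus when perfusion output is enabled) is rendered and
analyzed by the same analysis modules a recorded dataset would pass
through. Titration runs at each lateral onset and its PEEP carries over
into the following supine step. Cohorts use independent seeds with modest
jitter on total compliance (±8 %), tidal volume (±8 %) and injury pressure
offsets — between-animal variability. Per-step summaries report PEEP, ΔP
(a ventilator/physiology reading, not re-estimated from frames),
`C_rs = V_T/ΔP`, the ventilation distributions, `C_Z` per half, EELI per
quadrant, optional perfusion shares, and the oxygenation surrogate;
compliance values are computed per subject and then averaged (ratios of
means would differ).

The paired-samples *t* statistic is `mean(d) / (sd(d)/√n)` with `df = n−1`
and a two-sided p-value; quadrant change reports give per-quadrant paired
comparisons of each lateral step against its preceding supine step, with
quadrants labeled dependent/non-dependent by posture. Omnibus
repeated-measures testing is intentionally not reimplemented; the report
emits per-pair statistics only.

## Documented scenarios

- `ards_scenario` — the injured cohort: full injury, titration policy,
  V_T 350 mL, RR 30/min, initial PEEP 10, FiO2 1.0, I:E 1:2. Under these
  conditions roughly a third of the dorsal compliance mass is collapsed at
  Supine 1 and the oxygenation surrogate sits below 100 mmHg.
- `ards_perfusion_scenario` — the same with one bolus per step (the study
  acquired perfusion in a subset of animals; cohort size is a parameter).
- `geometric_shift_scenario` — a constructed mechanism scenario isolating
  the paradoxical dependent-lung EELI split: derecruitment disabled
  (healthy thresholds), lateral PEEP scheduled at +4 cmH2O instead of
  titrated, pleural gradient 0.85 cmH2O/cm. Geometry alone then dictates
  the pattern: the dependent-*ventral* quadrant swings deepest under
  rotation and loses more `P_L` than the PEEP increment restores (EELI
  falls), while the dependent-*dorsal* quadrant, closer to the rotation
  pivot, comes out ahead (EELI rises) and both non-dependent quadrants
  gain. In the fully injured, titrated scenario the larger PEEP increments
  (+4 to +6 cmH2O) overwhelm the geometric penalty and both dependent
  quadrants gain EELI; the split is therefore demonstrated in the scenario
  built to exhibit it, which is the honest reading of a mechanism that in
  vivo emerges from effects (mediastinal weight, abdominal loading,
  thoracic-wall restriction) this simulator does not model.
- `titration_scenario` — the closed-form titration benchmark above.

## What the simulator does and does not emulate

It emulates: 50 Hz pixel-image EIT with body-fixed ROIs, tidal and cardiac
impedance components with sensor noise, gravity- and posture-dependent
collapse with opening/closing hysteresis and minutes-scale derecruitment,
PEEP-dependent end-expiratory volume, first-pass saline-bolus transients,
shunt-coupled oxygenation, and between-animal variability. It does not
emulate: electrode-level voltages or image reconstruction, absolute
impedance calibration drift, pendelluft or intra-breath gas
redistribution, mediastinal/abdominal mechanics (the in-vivo contributors
to the dependent-dorsal paradox), airway resistance or flow limitation,
hemodynamics, or blood-gas chemistry. Passing tests therefore demonstrate
that the *analysis pipeline* recovers known ground truth and that the
*mechanistic skeleton* (pleural gradient + hysteresis + titration)
reproduces the directional physiology; they are not a validation against
animal recordings.

## Numerical details

- Determinism: every random draw derives from `SimConfig.seed` via
  independent `SeedSequence` streams (model build, frame noise, scenario
  construction, cohort jitter); identical configuration gives bit-identical
  frames and identical summaries.
- Degenerate inputs: an all-collapsed lung raises (`ΔP` undefined); empty
  ROIs, zero total ΔZ, contrast-free bolus windows, apnea windows under
  10 s, a bolus outside apnea, unsorted or unpaired events, and non-uniform
  time axes are all rejected with descriptive errors.
- Tie-breaks: the first post-peak local minimum truncates the first pass;
  quadrant/half partitions are exact set partitions validated
  pixel-by-pixel; `opening = max(opening, closing)` enforces non-negative
  hysteresis after noise.
- Problem sizes in the shipped tests and acceptance script (60 s epochs,
  20-scenario recovery batteries, 7-subject cohorts, 1000-replicate null
  calibration) were chosen so the full suite runs in well under an hour on
  a single CPU while keeping every statistical margin wide; all are
  parameters, not constants.
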