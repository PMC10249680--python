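# Methods

## The measurement

A relative afferent pupillary defect (RAPD) is an asymmetry of the afferent
pupillary pathways. The swinging-flashlight test alternates a light between
the eyes; because the reflex is consensual (both pupils respond to either
eye's input), a pupil that dilates when the light swings to it betrays an
afferent deficit in that eye. The VR version replays a fixed schedule of
monocular stimuli at several attenuation levels and quantifies the deficit
as a regression x-intercept, in log units of attenuation.

### Protocols

A protocol is expanded into *illumination levels*: level 1 stimulates both
eyes at 100% of the device baseline (97.8 cd/m² for the Vive-like profile,
97.2 for the FOVE-like one); each attenuation fraction `f < 1` contributes a
right-attenuated level (right at `f`, left at 100%) and then its mirror.
Each level is swung `repetitions` times, right eye first, with
`light_duration` seconds per eye. All protocols open with 5 s of darkness
for dark adaptation.

| protocol | fractions | light (s) | reps | levels | total |
|---|---|---|---|---|---|
| 1 | 1, 0.5, 0.25 | 3 | 3 | 5 | 95 s |
| 2 | 1, 0.5, 0.25 | 2 | 3 | 5 | 65 s |
| 3 | 1.0 … 0.1 step 0.1 | 2 | 4 | 19 | 399 s |

Protocol 3 inserts 5 s of darkness between consecutive levels (18 rest
periods), read as "between iterations" of the level sequence rather than
between repetitions; both the 2 s light duration and the rest placement are
config overrides. Under these constants the protocol-3 total reconstructs
to 399 s (5 + 19·4·2·2 + 18·5); the commonly quoted round figure of 400 s is
not exactly reproducible from any single reading of the stated parameters,
and we report the reconstructed value.

Attenuations convert to log units as `a = −log10(fraction)`; 0.5 → 0.301 and
0.25 → 0.602, i.e. the 0.3 / 0.6 neutral-density-filter steps.

## Reflex simulator

The generator is deliberately minimal: the simplest dynamics that make
constriction amplitude approximately linear in log-unit attenuation over the
protocols' range, which is the property the scoring regression relies on.

- **Afferent drive.** `E(t) = (I_R·10^(−d_R) + I_L·10^(−d_L)) / 2`, with
  `d_R, d_L ≥ 0` the per-eye deficits in log units. A deficit is a pure
  afferent log-attenuation — exactly the mechanism by which an artificial
  RAPD is induced with reduced stimulus illumination — so the balance point
  of the left/right comparison, and hence the ground-truth x-intercept, is
  `Δ = d_R − d_L` by construction. Binocular summation is an arithmetic
  mean; only one eye is lit at a time, so this choice only scales
  amplitudes.
- **Steady state.** Logistic in log luminance:
  `D_ss(E) = d_min + (d_max − d_min) / (1 + exp(slope·(log10 E − half_lum)))`,
  defaults `d_max = 7 mm`, `d_min = 2 mm`, `slope = 1.5`, `half_lum = 1.0`
  (midpoint at 10 cd/m²). A `1e−6 cd/m²` floor guards the log in darkness.
- **Dynamics.** First-order lag `dD/dt = (D_ss(E(t − latency)) − D)/τ`,
  latency 0.25 s, `τ_constrict = 0.4 s`, `τ_dilate = 1.2 s` — typical human
  PLR orders of magnitude, with the physiological constriction/redilation
  asymmetry. Because the delayed drive is piecewise constant, the equation
  is solved exactly per constant-drive segment (no Euler error), sampled at
  120 Hz.
- **Noise** (defaults chosen once as realistic for consumer VR eye
  tracking): per-eye white noise SD 0.05 mm; shared hippus 0.1 mm at 0.2 Hz
  with random phase; blinks as a 0.25 Hz Poisson process with uniform
  0.1–0.4 s durations, invalidating both eyes (sentinel −1 mm); a
  once-per-session Gaussian gain (SD 0.05) on the diameter range. Gaze
  columns are fixation plus jitter, present only for schema fidelity.
- **Cohorts.** Subject deficits are drawn once (default
  `Normal(0, 0.15)` truncated at ±0.45 log units — the SD of a control
  population whose scores fall mostly inside the ±0.3 normal range, capped
  at the extreme score a control plausibly produces) and held fixed across
  sessions; noise and gain are redrawn per session. An optional
  `session_deficit_sd` jitters the effective deficit per session: the
  session gain alone cannot create test–retest score variance because the
  score is invariant to scaling all amplitudes, so day-to-day afferent
  variability needs its own knob (study emulation default 0.05 log units).

What the generator does **not** emulate: anisocoria and efferent defects,
pharmacological effects, accommodation-driven pupil change, gaze-dependent
tracking loss, and any nonlinearity of real sensor noise. A green
recovery test therefore establishes that the pipeline's estimator is
consistent with its own forward model — not that it is unbiased on real
headset data.

## Preprocessing

- **Masking** flags, per eye, diameters outside (1, 10) mm or nonpositive
  sentinels, and samples jumping more than 0.5 mm from the preceding
  in-range sample (the jump rule compares only adjacent in-range samples so
  a lone sentinel does not condemn its neighbour). Values are never
  modified; masking is idempotent.
- **Gap repair** linearly interpolates invalid runs up to 0.5 s with valid
  anchors on both sides, marking samples imputed; longer and edge gaps stay
  invalid.
- **Epoching** cuts one epoch per illuminated event. The analyzed signal is
  the mean of the two pupils (consensual reflex; halves sensor noise and is
  agnostic to which eye the device tracks better — a stimulated-eye-only
  option exists). Baseline = median over the 0.5 s before onset (robust to
  blinks); amplitude = baseline − window minimum, floored at 0 — the
  simplest estimator of "difference in contraction amplitude". Epochs with
  more than 30% invalid samples are rejected; sessions with more than 25%
  rejected analyzable epochs are unusable.
- **Adaptation swings.** The first repetition of every level is excluded by
  default. This is a deliberate design choice, made on the model's own
  arithmetic: the first swing of a level inherits the previous light state
  (dark adaptation at level 1, the previous level's attenuation elsewhere),
  and because amplitudes floor at zero the inherited transient rectifies
  into a one-sided bias — with all repetitions kept, a perfectly symmetric
  noiseless subject scores ≈ −0.10 instead of 0 under protocol 1. Dropping
  repetition 1 restores the antisymmetry of the level responses and the
  pipeline recovers injected deficits to within ±0.02 log units across the
  ±0.6 grid. Exclusions are flags, not omissions, and do not count against
  session usability.

## Scoring

Per level, `y = mean amplitude (right stim) − mean amplitude (left stim)`
over accepted epochs, `x = a_L − a_R`. The sign pair is the unique
assignment under which a positive x-intercept means a right-eye defect:
attenuating the left stimulus (x > 0) weakens left-stim responses, so y
rises with x with positive slope, and y crosses zero where the protocol's
attenuation exactly compensates the deficit.

Unweighted OLS over level means is the default (a count-weighted fit and a
per-repetition variant are options; with balanced designs they coincide).
`score = −intercept/slope`, reported unclipped. Fits with fewer than 3
levels or no x spread are errors; fits with |slope| < 0.05 mm/log-unit are
flagged unusable (the intercept of a near-flat line is numerically
meaningless) rather than given a wild score. Laterality: right if
score > 0.3, left if score < −0.3, else none.

## Reliability

From the two-way ANOVA without replication (subjects × occasions; mean
squares MS_R, MS_C, MS_E on n−1, k−1, (n−1)(k−1) df), the McGraw–Wong
single-measurement forms:

- ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E) — ignores a fixed occasion
  offset. 95% CI by the exact F pivot.
- ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + (k/n)(MS_C − MS_E)) —
  penalises the offset. 95% CI by the Satterthwaite-df approximation.
- Both report F = MS_R/MS_E on (n−1, (n−1)(k−1)) df against ICC = 0.

The "mixed vs random" distinction affects interpretation, not these point
estimates. Note that ICC(A,1) is *not* always below ICC(C,1): its
denominator adds `(k/n)(MS_C − MS_E)`, which is negative whenever the sample
occasion mean square falls below the error mean square, so the two can
invert on ordinary data; the familiar ordering holds exactly when
MS_C ≥ MS_E. Matrices use complete cases only (listwise deletion, counted).
Degenerate inputs (zero total variance) are flagged undefined rather than
reported as 1.

Bland–Altman: differences `t1 − t2` against means `(t1 + t2)/2`; bias = mean
difference; limits of agreement = bias ± 1.96·SD (SD with n−1; the 1.96
multiplier is fixed, not a t quantile); the bias CI is t-based,
`bias ± t(0.975, n−1)·SD/√n`.

Interpretation scales (lower bin edges inclusive): Cicchetti — poor < 0.4 ≤
fair < 0.6 ≤ good < 0.75 ≤ excellent; Koo–Li — poor < 0.5 ≤ moderate <
0.75 ≤ good < 0.9 ≤ excellent.

## Study emulation

`run_study` draws one subject pool (deficits fixed per subject), measures
the first `n` subjects of the pool in each device-protocol arm for two
sessions, scores every session, and emits: a long scores table, a
test–retest reliability table (both ICC forms + Bland–Altman per arm),
between-arm reliability on genuinely shared subjects (session-1 scores),
Bland–Altman point sets, five-number score summaries with 1.5·IQR outliers,
an attrition log, and a YAML config snapshot. Everything derives from one
master seed via seed-sequence spawning, so two runs with the same config are
file-for-file identical.

## Numerical and design notes

- Events are half-open `[start, end)` in seconds from session start;
  schedules are replayed sample-by-sample at the trace's rate.
- The simulator's exact exponential stepping makes noiseless traces
  reproducible to the last bit across platforms; CSV round trips are
  byte-identical because floats are serialised at a fixed 6 decimals.
- Level ordering (right-attenuated before left-attenuated) is cosmetic:
  levels are keyed by index, never by position.
- The regression's residual nonlinearity (the logistic steady state is only
  locally linear in log attenuation) contributes ≲ 0.012 log units of
  systematic score error over the ±0.6 grid — inside the ±0.02 recovery
  tolerance and far below between-session noise.

## Limitations

- The generator's realism budget is spent on the properties the estimator
  uses (amplitude-vs-attenuation linearity, consensual symmetry, blink
  structure); absolute amplitudes and latencies are plausible but not fitted
  to any dataset.
- Reliability magnitudes produced by the default emulation (ICC ≈ 0.85–0.9)
  characterise the synthetic world's noise budget, not any particular
  headset's; they are deliberately in the "good" range so that both
  interpretation scales exercise non-trivial bins.
- Session usability thresholds (30% epoch, 25% session) are conventions,
  exposed as configuration, not estimates from data.
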