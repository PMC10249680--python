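# vrsft

Analysis tooling for the **VR swinging-flashlight test (VR-SFT)**: an
automated, headset-based version of the classic bedside test for a
**relative afferent pupillary defect (RAPD)** — an asymmetry between the two
eyes' afferent pupillary pathways, quantified in log units of stimulus
attenuation.

The package is aimed at pupillometry researchers who need the measurement
and agreement machinery of such a study without headset hardware or human
subjects. It provides:

- **Stimulus protocols** — three alternating-light schedules (5 or 19
  illumination levels, attenuations expressed as fractions of the device
  baseline and as log units: 50% ≙ 0.3, 25% ≙ 0.6 log units), built as
  explicit timed event plans.
- **A pupillary-light-reflex simulator** — binocular recordings with a known
  induced deficit, consensual responses, hippus, sensor noise, blink
  dropouts and session-to-session variability, emitted in the eye-tracker
  CSV schema (timestamps, per-eye intensity, pupil diameters, gaze,
  validity).
- **Preprocessing** — validity masking, short-gap interpolation, epoch
  segmentation against a schedule, constriction-amplitude extraction.
- **RAPD scoring** — per level, the difference in constriction amplitude
  between right- and left-eye stimulation, `y` (mm), is regressed on the
  level's signed attenuation `x = a_L − a_R` (log units, `a_e =
  −log10(fraction_e)`). The OLS line `y = β₀ + β₁x` crosses the x-axis where
  the two eyes' responses balance:

  ```
  RAPD score = −β₀ / β₁
  ```

  Positive scores localise the defect to the right eye, negative to the
  left; (−0.3, +0.3) log units is the conventional normal range.
- **Reliability analysis** — two-way mixed-effects single-measurement ICCs
  after McGraw & Wong, ICC(C,1) (consistency) and ICC(A,1) (absolute
  agreement), with 95% CIs and F tests, plus Bland–Altman bias and 1.96·SD
  limits of agreement, and the Cicchetti and Koo–Li interpretation scales.
- **Study emulation** — `run_study` reproduces a five-arm, two-session
  test–retest design (two device profiles × protocols, completer counts
  27/27/26/20/20) end to end from one master seed.

## Worked example

`examples/score_session.py` simulates a noisy protocol-1 session for a
subject with a 0.45 log-unit left-eye deficit and scores it:

```
epochs: 30 total, 0 rejected (blinks), 10 excluded (adaptation swings)
  level 1: x = +0.000 log units, y = +0.824 mm (n = 2+2)
  level 2: x = -0.301 log units, y = +0.135 mm (n = 2+2)
  level 3: x = +0.301 log units, y = +1.313 mm (n = 2+2)
  level 4: x = -0.602 log units, y = -0.324 mm (n = 2+2)
  level 5: x = +0.602 log units, y = +1.626 mm (n = 2+2)
RAPD score = -0.424 log units (slope 1.69 mm/log-unit, r^2 = 0.986)
laterality: left (negative score = left-eye defect; normal range is +-0.3)
```

Each `y` is the mean right-stim minus left-stim constriction amplitude at
that level; the fitted line crosses zero near the injected −0.45, so the
regression recovers the simulated deficit and flags the left eye. The other
examples cover protocol timing (`protocol_schedules.py`), the CSV round trip
(`simulate_session.py`), cohort reliability (`test_retest_reliability.py`)
and the full study emulation (`full_study.py`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

runs the complete pipeline — simulates the five-condition test–retest
cohort, preprocesses and scores every session, and computes the full
reliability report — and writes its JSON result file.

See `docs/methods.md` for the reflex model, the scoring and agreement
formulas, parameter defaults and known limitations.
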