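"""Preprocess and score a session: from raw trace to RAPD score.

Shows the per-level regression points (signed log-unit attenuation vs
response difference) and the fitted line whose x-intercept is the score.
"""

from vrsft import (
    NoiseParams, SubjectParams, build_protocol, interpolate_gaps,
    level_responses, levels_from_schedule, mask_invalid, rapd_score,
    schedule_events, segment_epochs, simulate_session,
)

schedule = schedule_events(build_protocol(1, "vive"))
subject = SubjectParams(deficit_left=0.45)  # true RAPD = -0.45 (left eye)
trace = simulate_session(schedule, subject, NoiseParams(), seed=7)

masked = mask_invalid(trace)
repaired = interpolate_gaps(masked)
epochs = segment_epochs(repaired, schedule)
print(f"epochs: {len(epochs)} total, "
      f"{sum(e.rejected for e in epochs)} rejected (blinks), "
      f"{sum(e.excluded for e in epochs)} excluded (adaptation swings)")

responses = level_responses(epochs, levels_from_schedule(schedule))
for r in responses:
    print(f"  level {r.level_index}: x = {r.x:+.3f} log units, "
          f"y = {r.y:+.3f} mm (n = {r.n_right}+{r.n_left})")

result = rapd_score(responses)
print(f"RAPD score = {result.score:+.3f} log units "
      f"(slope {result.slope:.2f} mm/log-unit, r^2 = {result.r_squared:.3f})")
print(f"laterality: {result.laterality} "
      f"(negative score = left-eye defect; normal range is +-0.3)")
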