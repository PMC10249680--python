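"""Simulate one noisy recording session with a known induced deficit.

Writes the session to the eye-tracker CSV schema and reads it back, showing
the round trip and basic trace properties.
"""

import tempfile
from pathlib import Path

from vrsft import (
    NoiseParams, SubjectParams, build_protocol, read_session,
    schedule_events, simulate_session, write_session,
)

schedule = schedule_events(build_protocol(2, "fove"))
subject = SubjectParams(deficit_right=0.3)  # 0.3 log-unit right-eye RAPD
trace = simulate_session(schedule, subject, NoiseParams(), seed=42)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "subject01_session1_fove_p2.csv"
    write_session(trace, path)
    back = read_session(path)
    print(f"wrote {path.name}: {len(back)} samples over "
          f"{back.time_s[-1]:.2f} s at 120 Hz")

n_invalid = int((~trace.valid_right).sum())
print(f"valid samples: {len(trace) - n_invalid}/{len(trace)} "
      f"({n_invalid} blink-dropout samples at -1 mm)")
print(f"pupil diameter range (valid): "
      f"{trace.right_pupil_mm[trace.valid_right].min():.2f}-"
      f"{trace.right_pupil_mm[trace.valid_right].max():.2f} mm")

# Both pupils respond to the same binocular drive (the reflex is consensual),
# so the right-eye deficit shows up as weaker constriction whenever the
# *right* eye is the one illuminated - the swinging-flashlight signature.
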