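"""Build the three swinging-flashlight protocols and inspect their timing.

Prints, per protocol: the illumination levels with their log-unit
attenuations, the number of swings, and the total session duration.
"""

from vrsft import build_protocol, enumerate_levels, schedule_events, total_duration

for pid in (1, 2, 3):
    spec = build_protocol(pid, device_baseline="vive")
    levels = enumerate_levels(spec)
    schedule = schedule_events(spec)
    print(f"protocol {pid}: {len(levels)} illumination levels, "
          f"{len(schedule.illuminated_events) // 2} swings, "
          f"total {total_duration(schedule):.0f} s")
    if pid == 1:
        for lv in levels:
            print(f"  level {lv.level_index}: right {lv.right_fraction:.0%}, "
                  f"left {lv.left_fraction:.0%}, x = {lv.signed_attenuation_x:+.3f} log units")

# The x column is the level's abscissa in the RAPD regression: x = aL - aR,
# positive when the left-eye stimulus is attenuated.  Protocols 1/2 span
# +-0.6 log units in two steps; protocol 3 spans +-1.0 in 0.1-fraction steps.
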