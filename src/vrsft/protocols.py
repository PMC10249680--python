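"""Swinging-flashlight stimulus protocols for VR pupillometry.

A protocol is a timed plan of alternating monocular light stimuli.  Each
*illumination level* pairs an attenuation fraction for the right eye with one
for the left eye (at most one eye is attenuated per level); a *swing* lights
the right eye for ``light_duration_s`` seconds, then the left eye.  Levels are
swung ``repetitions_per_level`` times.  Attenuations are expressed both as
fractions of the device's initial luminance and in log units
(``-log10(fraction)``), the unit in which neutral density filters and RAPD
scores are stated: a 0.3 log-unit filter halves intensity, 0.6 quarters it.

Three protocols are built in:

======== =========================== ========== ===== ==========
protocol fractions                   light (s)  reps  levels
======== =========================== ========== ===== ==========
1        1, 0.5, 0.25                3          3     5
2        1, 0.5, 0.25                2          3     5
3        1, 0.9, ..., 0.1            2          4     19
======== =========================== ========== ===== ==========

All protocols begin with 5 s of darkness for dark adaptation; protocol 3
additionally rests the eyes with 5 s of darkness between consecutive levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "IlluminationLevel",
    "ProtocolSpec",
    "ScheduleEvent",
    "StimulusSchedule",
    "DEVICE_BASELINES",
    "log_attenuation",
    "build_protocol",
    "enumerate_levels",
    "schedule_events",
    "total_duration",
    "write_schedule_csv",
    "read_schedule_csv",
]

#: Initial (unattenuated) stimulus luminance per device profile, cd/m^2.
DEVICE_BASELINES = {"vive": 97.8, "fove": 97.2}

RIGHT = "right"
LEFT = "left"
NONE = "none"


def log_attenuation(fraction: float) -> float:
    """Log-unit attenuation of an intensity fraction: ``-log10(fraction)``.

    A fraction of 0.5 is a 0.301 (~0.3) log-unit attenuation, 0.25 is 0.602
    (~0.6) — the neutral-density-filter equivalents of the built-in protocols.

    Raises
    ------
    ValueError
        If ``fraction`` is not strictly positive.
    """
    if fraction <= 0:
        raise ValueError(f"intensity fraction must be > 0, got {fraction}")
    return -math.log10(fraction)


@dataclass(frozen=True)
class IlluminationLevel:
    """One illumination level: per-eye attenuation fractions and its x-coordinate.

    ``signed_attenuation_x`` is the level's abscissa in the RAPD regression:
    ``x = a_L - a_R`` with ``a_e = -log10(fraction_e)``.  Positive x means the
    left-eye stimulus is attenuated relative to the right.
    """

    level_index: int
    right_fraction: float
    left_fraction: float

    def __post_init__(self) -> None:
        if self.right_fraction <= 0 or self.left_fraction <= 0:
            raise ValueError("illumination fractions must be strictly positive")
        if self.right_fraction != 1.0 and self.left_fraction != 1.0:
            raise ValueError("at most one eye may be attenuated within a level")

    @property
    def signed_attenuation_x(self) -> float:
        return log_attenuation(self.left_fraction) - log_attenuation(self.right_fraction)


@dataclass(frozen=True)
class ProtocolSpec:
    """Parameters of one swinging-flashlight protocol."""

    protocol_id: int
    intensity_fractions: tuple[float, ...]
    light_duration_s: float
    repetitions_per_level: int
    dark_adaptation_delay_s: float = 5.0
    inter_iteration_dark_s: float = 0.0
    initial_luminance_cd_m2: float = DEVICE_BASELINES["vive"]


@dataclass(frozen=True)
class ScheduleEvent:
    """One contiguous stimulus state: ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    stimulated_eye: str  # "right" | "left" | "none"
    right_fraction: float
    left_fraction: float
    level_index: int  # 0 for dark events
    repetition_index: int  # 1-based; 0 for dark events

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("event must have positive duration")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered, non-overlapping sequence of stimulus events."""

    protocol_id: int
    events: tuple[ScheduleEvent, ...]
    initial_luminance_cd_m2: float = DEVICE_BASELINES["vive"]

    @property
    def illuminated_events(self) -> tuple[ScheduleEvent, ...]:
        return tuple(e for e in self.events if e.stimulated_eye != NONE)


_PROTOCOL_TABLE = {
    1: dict(fractions=(1.0, 0.5, 0.25), light_duration_s=3.0, reps=3, inter_dark=0.0),
    2: dict(fractions=(1.0, 0.5, 0.25), light_duration_s=2.0, reps=3, inter_dark=0.0),
    # Protocol 3: 10% steps, four repetitions, 5 s dark rest between levels.
    # The light duration follows the protocol description (2 s), which also
    # reconciles with the stated ~400 s total; it can be overridden.
    3: dict(
        fractions=tuple(round(1.0 - 0.1 * i, 1) for i in range(10)),
        light_duration_s=2.0,
        reps=4,
        inter_dark=5.0,
    ),
}


def build_protocol(
    protocol_id: int,
    device_baseline: float | str = "vive",
    *,
    light_duration_s: float | None = None,
    inter_iteration_dark_s: float | None = None,
) -> ProtocolSpec:
    """Build one of the three standard protocols.

    Parameters
    ----------
    protocol_id
        1, 2 or 3.
    device_baseline
        Initial stimulus luminance in cd/m^2, or a device profile name
        (``"vive"`` → 97.8, ``"fove"`` → 97.2).
    light_duration_s, inter_iteration_dark_s
        Optional overrides of the protocol constants.
    """
    if protocol_id not in _PROTOCOL_TABLE:
        raise ValueError(f"unknown protocol_id {protocol_id!r}; expected 1, 2 or 3")
    if isinstance(device_baseline, str):
        try:
            device_baseline = DEVICE_BASELINES[device_baseline.lower()]
        except KeyError:
            raise ValueError(
                f"unknown device profile {device_baseline!r}; "
                f"expected one of {sorted(DEVICE_BASELINES)}"
            ) from None
    row = _PROTOCOL_TABLE[protocol_id]
    spec = ProtocolSpec(
        protocol_id=protocol_id,
        intensity_fractions=row["fractions"],
        light_duration_s=row["light_duration_s"],
        repetitions_per_level=row["reps"],
        inter_iteration_dark_s=row["inter_dark"],
        initial_luminance_cd_m2=float(device_baseline),
    )
    if light_duration_s is not None:
        spec = replace(spec, light_duration_s=float(light_duration_s))
    if inter_iteration_dark_s is not None:
        spec = replace(spec, inter_iteration_dark_s=float(inter_iteration_dark_s))
    return spec


def enumerate_levels(spec: ProtocolSpec) -> list[IlluminationLevel]:
    """Expand a protocol's fractions into its ordered illumination levels.

    Level 1 is the equal-illumination baseline (both eyes at 100%).  Each
    attenuation fraction f < 1 contributes two levels — f on the right eye
    (left at 100%) first, then f on the left eye — in order of increasing
    attenuation.  Protocols 1-2 therefore have 5 levels, protocol 3 has 19.
    """
    attenuated = sorted((f for f in spec.intensity_fractions if f != 1.0), reverse=True)
    levels = [IlluminationLevel(1, 1.0, 1.0)]
    idx = 2
    for f in attenuated:
        levels.append(IlluminationLevel(idx, f, 1.0))
        levels.append(IlluminationLevel(idx + 1, 1.0, f))
        idx += 2
    return levels


def schedule_events(spec: ProtocolSpec) -> StimulusSchedule:
    """Lay a protocol out as a timed event schedule.

    The schedule opens with ``dark_adaptation_delay_s`` of darkness; each
    (level, repetition) then contributes one right-eye event followed by one
    left-eye event of ``light_duration_s`` each.  Protocols with
    ``inter_iteration_dark_s > 0`` insert that much darkness between
    consecutive levels (not between repetitions).
    """
    levels = enumerate_levels(spec)
    events: list[ScheduleEvent] = []
    t = 0.0
    if spec.dark_adaptation_delay_s > 0:
        events.append(
            ScheduleEvent(t, spec.dark_adaptation_delay_s, NONE, 0.0, 0.0, 0, 0)
        )
        t = spec.dark_adaptation_delay_s
    for i, level in enumerate(levels):
        if i > 0 and spec.inter_iteration_dark_s > 0:
            events.append(
                ScheduleEvent(t, t + spec.inter_iteration_dark_s, NONE, 0.0, 0.0, 0, 0)
            )
            t += spec.inter_iteration_dark_s
        for rep in range(1, spec.repetitions_per_level + 1):
            for eye, rf, lf in (
                (RIGHT, level.right_fraction, 0.0),
                (LEFT, 0.0, level.left_fraction),
            ):
                events.append(
                    ScheduleEvent(
                        t, t + spec.light_duration_s, eye, rf, lf,
                        level.level_index, rep,
                    )
                )
                t += spec.light_duration_s
    return StimulusSchedule(
        protocol_id=spec.protocol_id,
        events=tuple(events),
        initial_luminance_cd_m2=spec.initial_luminance_cd_m2,
    )


def total_duration(schedule: StimulusSchedule) -> float:
    """End time of the schedule's last event, in seconds from session start."""
    if not schedule.events:
        raise ValueError("schedule has no events")
    return schedule.events[-1].end_s


# ---------------------------------------------------------------------------
# Schedule CSV round trip

_SCHEDULE_COLUMNS = [
    "start_s", "end_s", "stimulated_eye", "right_fraction", "left_fraction",
    "level_index", "repetition_index",
]


def write_schedule_csv(schedule: StimulusSchedule, path) -> None:
    df = pd.DataFrame(
        [
            (e.start_s, e.end_s, e.stimulated_eye, e.right_fraction,
             e.left_fraction, e.level_index, e.repetition_index)
            for e in schedule.events
        ],
        columns=_SCHEDULE_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_schedule_csv(path, protocol_id: int = 0,
                      initial_luminance_cd_m2: float = DEVICE_BASELINES["vive"]
                      ) -> StimulusSchedule:
    df = pd.read_csv(path)
    missing = [c for c in _SCHEDULE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"schedule CSV missing columns: {missing}")
    events = tuple(
        ScheduleEvent(
            float(r.start_s), float(r.end_s), str(r.stimulated_eye),
            float(r.right_fraction), float(r.left_fraction),
            int(r.level_index), int(r.repetition_index),
        )
        for r in df.itertuples()
    )
    return StimulusSchedule(protocol_id, events, initial_luminance_cd_m2)
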