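"""Synthetic binocular pupillary-light-reflex recordings.

The generator stands in for headset eye-tracker exports: it replays a
:class:`~vrsft.protocols.StimulusSchedule` through a minimal reflex model and
emits per-sample timestamps, per-eye stimulus intensity, pupil diameters, gaze
and validity flags — the same columns a VR swinging-flashlight session writes.

Model
-----
Both pupils track a common effective luminance

    E(t) = (I_R(t) * 10**(-d_R) + I_L(t) * 10**(-d_L)) / 2,

where ``d_R, d_L >= 0`` are the eyes' afferent deficits in log units — a pure
afferent attenuation, mirroring how an artificial RAPD is induced by reducing
one eye's stimulus.  The induced true RAPD is ``delta = d_R - d_L``, and by
construction the balance point of the swinging-light comparison (hence the
downstream regression x-intercept) equals ``delta``.

The diameter relaxes toward a logistic steady state of log-luminance,

    D_ss(E) = d_min + (d_max - d_min) / (1 + exp(slope * (log10 E - half_lum))),

with first-order dynamics ``dD/dt = (D_ss(E(t - latency)) - D) / tau`` using a
faster constriction than redilation time constant.  On top of the noiseless
reflex the simulator adds shared hippus (a slow sinusoid with random phase),
per-eye white measurement noise, Poisson blink dropouts that invalidate both
eyes, and a once-per-session multiplicative gain on the diameter range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .protocols import StimulusSchedule, total_duration

__all__ = [
    "SubjectParams",
    "NoiseParams",
    "PupilTrace",
    "DeficitSampler",
    "CohortSession",
    "steady_state_diameter",
    "effective_luminance",
    "simulate_session",
    "simulate_cohort",
]

#: Luminance floor guarding log10 of darkness, cd/m^2.
_E_FLOOR = 1e-6

#: Sentinel diameter recorded during blinks.
BLINK_SENTINEL_MM = -1.0


@dataclass(frozen=True)
class SubjectParams:
    """Reflex-model parameters of one simulated subject.

    Deficits are log-unit afferent attenuations (0 = healthy eye); the induced
    RAPD is ``deficit_right - deficit_left``.  Diameter bounds are in mm, the
    latency and time constants in seconds.
    """

    deficit_right: float = 0.0
    deficit_left: float = 0.0
    d_max: float = 7.0
    d_min: float = 2.0
    slope: float = 1.5
    half_lum: float = 1.0
    latency_s: float = 0.25
    tau_constrict_s: float = 0.4
    tau_redilate_s: float = 1.2

    def __post_init__(self) -> None:
        if not (self.d_max > self.d_min > 0):
            raise ValueError("require d_max > d_min > 0")
        if self.tau_constrict_s <= 0 or self.tau_redilate_s <= 0:
            raise ValueError("time constants must be positive")
        if self.deficit_right < 0 or self.deficit_left < 0:
            raise ValueError("deficits are log-unit attenuations, must be >= 0")

    @property
    def true_rapd(self) -> float:
        return self.deficit_right - self.deficit_left


@dataclass(frozen=True)
class NoiseParams:
    """Measurement/physiological noise configuration.

    Defaults are typical of consumer VR eye tracking: ~0.05 mm white sensor
    noise, 0.1 mm hippus near 0.2 Hz, ~15 blinks/min of 100-400 ms, a few
    percent session-to-session amplitude gain, sampled at 120 Hz.
    """

    white_sd_mm: float = 0.05
    hippus_amp_mm: float = 0.1
    hippus_freq_hz: float = 0.2
    blink_rate_hz: float = 0.25
    blink_dur_range_s: tuple[float, float] = (0.1, 0.4)
    session_gain_sd: float = 0.05
    sample_rate_hz: float = 120.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        for name in ("white_sd_mm", "hippus_amp_mm", "hippus_freq_hz",
                     "blink_rate_hz", "session_gain_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @classmethod
    def none(cls, sample_rate_hz: float = 120.0) -> "NoiseParams":
        """A noiseless configuration (useful for parameter-recovery checks)."""
        return cls(0.0, 0.0, 0.0, 0.0, (0.0, 0.0), 0.0, sample_rate_hz)


@dataclass
class PupilTrace:
    """One session's samples: times, per-eye stimulus, diameters, gaze, validity.

    Invalid samples (blinks, dropouts) carry the sentinel diameter -1 mm and
    ``valid_* = False``.  ``imputed_*`` marks samples later filled in by gap
    interpolation; freshly simulated traces have none.
    """

    time_s: np.ndarray
    right_intensity_frac: np.ndarray
    left_intensity_frac: np.ndarray
    right_pupil_mm: np.ndarray
    left_pupil_mm: np.ndarray
    right_gaze_x: np.ndarray
    right_gaze_y: np.ndarray
    left_gaze_x: np.ndarray
    left_gaze_y: np.ndarray
    valid_right: np.ndarray
    valid_left: np.ndarray
    imputed_right: np.ndarray | None = None
    imputed_left: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.time_s)
        for name in ("right_intensity_frac", "left_intensity_frac",
                     "right_pupil_mm", "left_pupil_mm", "right_gaze_x",
                     "right_gaze_y", "left_gaze_x", "left_gaze_y",
                     "valid_right", "valid_left"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.imputed_right is None:
            self.imputed_right = np.zeros(n, dtype=bool)
        if self.imputed_left is None:
            self.imputed_left = np.zeros(n, dtype=bool)

    def __len__(self) -> int:
        return len(self.time_s)

    def copy(self) -> "PupilTrace":
        return PupilTrace(
            *(np.array(getattr(self, f), copy=True) for f in (
                "time_s", "right_intensity_frac", "left_intensity_frac",
                "right_pupil_mm", "left_pupil_mm", "right_gaze_x",
                "right_gaze_y", "left_gaze_x", "left_gaze_y",
                "valid_right", "valid_left", "imputed_right", "imputed_left"))
        )


def steady_state_diameter(effective_luminance, params: SubjectParams):
    """Steady-state pupil diameter (mm) at an effective luminance (cd/m^2).

    Logistic in log10 luminance: d_max in darkness, d_min under saturating
    light, midpoint at ``10**half_lum``.  Accepts scalars or arrays.
    """
    e = np.maximum(np.asarray(effective_luminance, dtype=float), _E_FLOOR)
    z = params.slope * (np.log10(e) - params.half_lum)
    out = params.d_min + (params.d_max - params.d_min) / (1.0 + np.exp(z))
    return float(out) if np.isscalar(effective_luminance) else out


def effective_luminance(right_stim, left_stim, params: SubjectParams):
    """Binocular afferent drive: mean of the two deficit-attenuated inputs.

    Each eye's stimulus (cd/m^2) is attenuated by ``10**(-deficit)`` before
    averaging; both pupils respond to this common drive (direct = consensual).
    """
    right_stim = np.asarray(right_stim, dtype=float)
    left_stim = np.asarray(left_stim, dtype=float)
    e = (right_stim * 10.0 ** -params.deficit_right
         + left_stim * 10.0 ** -params.deficit_left) / 2.0
    return float(e) if e.ndim == 0 else e


def _stimulus_fractions(schedule: StimulusSchedule, t: np.ndarray):
    """Per-sample (right, left) intensity fractions replayed from the schedule."""
    starts = np.array([e.start_s for e in schedule.events])
    rf = np.array([e.right_fraction for e in schedule.events])
    lf = np.array([e.left_fraction for e in schedule.events])
    ends = np.array([e.end_s for e in schedule.events])
    idx = np.searchsorted(starts, t, side="right") - 1
    idx = np.clip(idx, 0, len(starts) - 1)
    right = np.where((t >= starts[idx]) & (t < ends[idx]), rf[idx], 0.0)
    left = np.where((t >= starts[idx]) & (t < ends[idx]), lf[idx], 0.0)
    return right, left


def _integrate_reflex(e_delayed: np.ndarray, dt: float, params: SubjectParams,
                      d_max_eff: float) -> np.ndarray:
    """Exact piecewise-exponential solution of the first-order reflex lag.

    The delayed drive is piecewise constant, so within each constant-drive run
    the diameter approaches its target exponentially with the constriction or
    redilation time constant, never overshooting; each run is solved in closed
    form on the sample grid.
    """
    eff = replace(params, d_max=d_max_eff) if d_max_eff != params.d_max else params
    d_ss = steady_state_diameter(np.maximum(e_delayed, 0.0), eff)
    n = len(d_ss)
    d = np.empty(n)
    d0 = eff.d_max  # dark-adapted start
    # boundaries of constant-drive runs
    change = np.flatnonzero(np.diff(d_ss) != 0.0) + 1
    bounds = np.concatenate(([0], change, [n]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        target = d_ss[a]
        tau = params.tau_constrict_s if target < d0 else params.tau_redilate_s
        k = np.arange(b - a)
        d[a:b] = target + (d0 - target) * np.exp(-(k * dt) / tau)
        d0 = target + (d0 - target) * math.exp(-((b - a) * dt) / tau)
    return d


def simulate_session(
    schedule: StimulusSchedule,
    subject: SubjectParams,
    noise: NoiseParams,
    seed,
) -> PupilTrace:
    """Simulate one recording session of a schedule for one subject.

    All randomness (session gain, hippus phase, sensor noise, gaze jitter,
    blinks) is driven by ``seed``; identical inputs give identical traces.
    """
    if not schedule.events:
        raise ValueError("schedule has no events")
    rng = np.random.default_rng(seed)
    fs = noise.sample_rate_hz
    dt = 1.0 / fs
    duration = total_duration(schedule)
    n = int(round(duration * fs))
    t = np.arange(n) * dt

    right_frac, left_frac = _stimulus_fractions(schedule, t)
    i0 = schedule.initial_luminance_cd_m2
    e = effective_luminance(right_frac * i0, left_frac * i0, subject)

    lag = int(round(subject.latency_s * fs))
    e_delayed = np.concatenate((np.zeros(lag), e[: n - lag])) if lag else e

    # draw order is fixed so seeds are reproducible across noise settings
    gain = max(0.1, float(rng.normal(1.0, noise.session_gain_sd)))
    d_max_eff = subject.d_min + gain * (subject.d_max - subject.d_min)
    d = _integrate_reflex(e_delayed, dt, subject, d_max_eff)

    phase = rng.uniform(0.0, 2.0 * np.pi)
    hippus = noise.hippus_amp_mm * np.sin(2.0 * np.pi * noise.hippus_freq_hz * t + phase)
    right = d + hippus + rng.normal(0.0, noise.white_sd_mm, n)
    left = d + hippus + rng.normal(0.0, noise.white_sd_mm, n)
    np.clip(right, 0.1, 10.0, out=right)
    np.clip(left, 0.1, 10.0, out=left)

    gaze_sd = 0.5  # deg; fixation jitter, schema fidelity only
    gx_r = rng.normal(0.0, gaze_sd, n)
    gy_r = rng.normal(0.0, gaze_sd, n)
    gx_l = rng.normal(0.0, gaze_sd, n)
    gy_l = rng.normal(0.0, gaze_sd, n)

    valid = np.ones(n, dtype=bool)
    n_blinks = rng.poisson(noise.blink_rate_hz * duration)
    if n_blinks > 0:
        onsets = np.sort(rng.uniform(0.0, duration, n_blinks))
        durs = rng.uniform(*noise.blink_dur_range_s, n_blinks)
        for onset, bd in zip(onsets, durs):
            valid[(t >= onset) & (t < onset + bd)] = False
    right[~valid] = BLINK_SENTINEL_MM
    left[~valid] = BLINK_SENTINEL_MM

    return PupilTrace(
        time_s=t,
        right_intensity_frac=right_frac,
        left_intensity_frac=left_frac,
        right_pupil_mm=right,
        left_pupil_mm=left,
        right_gaze_x=gx_r,
        right_gaze_y=gy_r,
        left_gaze_x=gx_l,
        left_gaze_y=gy_l,
        valid_right=valid.copy(),
        valid_left=valid.copy(),
    )


@dataclass(frozen=True)
class DeficitSampler:
    """Distribution of per-subject induced RAPDs (signed, log units).

    Draws delta ~ Normal(mean, sd) truncated to |delta| <= truncate by
    rejection; a positive delta is realised as a right-eye deficit, a negative
    one as a left-eye deficit.  The default emulates a control cohort whose
    scores fall mostly within the +-0.3 normal range, with the rare extreme
    capped at 0.45.
    """

    mean: float = 0.0
    sd: float = 0.15
    truncate: float = 0.45

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        out = rng.normal(self.mean, self.sd, n)
        if self.sd > 0:
            bad = np.abs(out) > self.truncate
            while bad.any():
                out[bad] = rng.normal(self.mean, self.sd, int(bad.sum()))
                bad = np.abs(out) > self.truncate
        else:
            out = np.clip(out, -self.truncate, self.truncate)
        return out


@dataclass
class CohortSession:
    """One simulated session with its ground-truth labels."""

    subject_id: str
    session_id: int
    true_delta: float  # subject-level induced RAPD, log units
    session_delta: float  # after per-session jitter (equals true_delta by default)
    trace: PupilTrace


def _deltas(deficit_sampler, rng: np.random.Generator, n: int) -> np.ndarray:
    if isinstance(deficit_sampler, DeficitSampler):
        return deficit_sampler.draw(rng, n)
    if callable(deficit_sampler):
        return np.asarray(deficit_sampler(rng, n), dtype=float)
    arr = np.broadcast_to(np.asarray(deficit_sampler, dtype=float), (n,))
    return np.array(arr, copy=True)


def simulate_cohort(
    n_subjects: int,
    deficit_sampler,
    schedule: StimulusSchedule,
    noise: NoiseParams,
    n_sessions: int,
    master_seed: int,
    *,
    subject_template: SubjectParams = SubjectParams(),
    session_deficit_sd: float = 0.0,
) -> list[CohortSession]:
    """Simulate a test-retest cohort: n_subjects x n_sessions labelled traces.

    Subject deficits are drawn once and held fixed across sessions; noise and
    the session gain are redrawn per session.  ``session_deficit_sd`` adds an
    optional per-session jitter to the effective deficit, modelling day-to-day
    afferent variability beyond amplitude gain (which the regression score is
    insensitive to).  Everything is deterministic under ``master_seed``.

    ``deficit_sampler`` may be a :class:`DeficitSampler`, a callable
    ``(rng, n) -> deltas``, a scalar, or a length-n sequence of deltas.
    """
    if n_subjects < 2 or n_sessions < 2:
        raise ValueError("reliability cohorts need n_subjects >= 2 and n_sessions >= 2")
    root = np.random.SeedSequence(master_seed)
    draw_ss, sess_ss = root.spawn(2)
    rng = np.random.default_rng(draw_ss)
    deltas = _deltas(deficit_sampler, rng, n_subjects)
    session_seeds = np.random.default_rng(sess_ss).integers(
        0, 2**31 - 1, size=(n_subjects, n_sessions)
    )
    jitter_rng = np.random.default_rng(root.spawn(1)[0])

    sessions: list[CohortSession] = []
    for i in range(n_subjects):
        for s in range(n_sessions):
            delta_s = float(deltas[i])
            if session_deficit_sd > 0:
                delta_s += float(jitter_rng.normal(0.0, session_deficit_sd))
            subject = replace(
                subject_template,
                deficit_right=max(delta_s, 0.0),
                deficit_left=max(-delta_s, 0.0),
            )
            trace = simulate_session(schedule, subject, noise,
                                     int(session_seeds[i, s]))
            sessions.append(
                CohortSession(
                    subject_id=f"S{i + 1:03d}",
                    session_id=s + 1,
                    true_delta=float(deltas[i]),
                    session_delta=delta_s,
                    trace=trace,
                )
            )
    return sessions
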