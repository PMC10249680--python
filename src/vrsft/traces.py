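"""Preprocessing of pupil traces: validity masking, gap repair, epoching.

The raw signal from a headset eye tracker carries blinks (sentinel values),
tracking dropouts and occasional spikes.  Preprocessing (1) flags implausible
samples, (2) linearly bridges short invalid gaps, and (3) cuts the trace into
one epoch per monocular stimulus event of the schedule, extracting the
constriction amplitude — pre-onset baseline minus the minimum diameter during
stimulation, in mm — that the RAPD regression consumes.

Epochs are never silently omitted: data-quality failures set ``rejected``,
and the deliberate drop of each level's first swing (the adaptation swing,
whose baseline still reflects the previous light state) sets ``excluded``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .plr_sim import PupilTrace
from .protocols import StimulusSchedule

__all__ = [
    "StimEpoch",
    "mask_invalid",
    "interpolate_gaps",
    "segment_epochs",
    "epoch_amplitude",
    "session_usable",
]

#: Plausible pupil diameter range, mm; samples outside are flagged invalid.
DIAMETER_RANGE_MM = (1.0, 10.0)

DEFAULT_JUMP_LIMIT_MM = 0.5
DEFAULT_MAX_GAP_S = 0.5
DEFAULT_BASELINE_WINDOW_S = 0.5
DEFAULT_REJECT_INVALID_FRAC = 0.30
DEFAULT_MAX_REJECTED_FRAC = 0.25


@dataclass
class StimEpoch:
    """One stimulus event's extracted response."""

    level_index: int
    repetition_index: int
    stimulated_eye: str
    onset_s: float
    offset_s: float
    baseline_mm: float  # median diameter over the pre-onset window
    min_mm: float  # minimum valid diameter in [onset, offset)
    amplitude_mm: float  # max(baseline - min, 0)
    fraction_invalid: float
    rejected: bool = False  # data-quality failure
    excluded: bool = False  # deliberate exclusion (adaptation swing)
    reason: str = ""

    @property
    def accepted(self) -> bool:
        return not (self.rejected or self.excluded)


def _eye_masks(trace: PupilTrace, jump_limit_mm: float):
    """New validity masks for both eyes from range and jump rules."""
    out = []
    for diam, valid in ((trace.right_pupil_mm, trace.valid_right),
                        (trace.left_pupil_mm, trace.valid_left)):
        ok = np.asarray(valid, dtype=bool).copy()
        in_range = (diam > DIAMETER_RANGE_MM[0]) & (diam < DIAMETER_RANGE_MM[1])
        ok &= in_range
        # jump rule between adjacent samples that both pass the range check,
        # so a lone sentinel does not condemn its neighbour
        adjacent_ok = in_range[1:] & in_range[:-1]
        jump = np.abs(np.diff(diam)) > jump_limit_mm
        bad_step = np.zeros(len(diam), dtype=bool)
        bad_step[1:] = adjacent_ok & jump
        ok &= ~bad_step
        out.append(ok)
    return out


def mask_invalid(trace: PupilTrace,
                 jump_limit_mm: float = DEFAULT_JUMP_LIMIT_MM) -> PupilTrace:
    """Flag implausible samples; values are never modified.

    A sample is invalidated per eye when its diameter is nonpositive (blink
    sentinel), outside (1, 10) mm, or jumps more than ``jump_limit_mm`` from
    the preceding in-range sample.  Idempotent.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    out = trace.copy()
    out.valid_right, out.valid_left = _eye_masks(trace, jump_limit_mm)
    return out


def _interp_eye(t, diam, valid, imputed, max_gap_s):
    diam = diam.copy()
    valid = valid.copy()
    imputed = imputed.copy()
    idx = np.flatnonzero(~valid)
    if idx.size:
        # split invalid samples into contiguous runs
        splits = np.flatnonzero(np.diff(idx) > 1) + 1
        for run in np.split(idx, splits):
            a, b = run[0], run[-1]
            if a == 0 or b == len(t) - 1:
                continue  # edge gap: no anchor on one side
            if not (valid[a - 1] and valid[b + 1]):
                continue
            if t[b + 1] - t[a - 1] > max_gap_s + 1e-12:
                continue
            diam[a:b + 1] = np.interp(t[a:b + 1],
                                      [t[a - 1], t[b + 1]],
                                      [diam[a - 1], diam[b + 1]])
            valid[a:b + 1] = True
            imputed[a:b + 1] = True
    return diam, valid, imputed


def interpolate_gaps(trace: PupilTrace,
                     max_gap_s: float = DEFAULT_MAX_GAP_S) -> PupilTrace:
    """Bridge invalid runs no longer than ``max_gap_s`` by linear interpolation.

    Only gaps with valid anchors on both sides are filled (per eye); filled
    samples become valid and are flagged imputed.  Longer gaps and edge gaps
    are untouched.  Running it again is the identity.
    """
    out = trace.copy()
    (out.right_pupil_mm, out.valid_right, out.imputed_right) = _interp_eye(
        out.time_s, out.right_pupil_mm, out.valid_right, out.imputed_right, max_gap_s)
    (out.left_pupil_mm, out.valid_left, out.imputed_left) = _interp_eye(
        out.time_s, out.left_pupil_mm, out.valid_left, out.imputed_left, max_gap_s)
    return out


def segment_epochs(
    trace: PupilTrace,
    schedule: StimulusSchedule,
    baseline_window_s: float = DEFAULT_BASELINE_WINDOW_S,
    reject_invalid_frac: float = DEFAULT_REJECT_INVALID_FRAC,
    *,
    eye: str = "mean",
    drop_first_repetition: bool = True,
) -> list[StimEpoch]:
    """Cut one epoch per illuminated schedule event and extract amplitudes.

    The analyzed diameter is the mean of the two eyes by default (the reflex
    is consensual, and averaging halves sensor noise); ``eye`` may instead
    name ``"right"`` or ``"left"``.  A sample enters the analysis only when
    the contributing eye(s) are valid.  ``baseline_mm`` is the median of the
    analyzed diameter over ``baseline_window_s`` before onset, ``min_mm`` the
    minimum within ``[onset, offset)``.

    Epochs whose stimulation window has more than ``reject_invalid_frac``
    invalid samples — or no usable baseline — are flagged ``rejected``.  With
    ``drop_first_repetition`` (default) the first swing of every level is
    flagged ``excluded``: its baseline reflects the *previous* light state
    (darkness before level 1, the previous level's attenuation otherwise),
    which biases the response asymmetrically.
    """
    events = schedule.illuminated_events
    if not events:
        raise ValueError("schedule has no illuminated events")
    t = trace.time_s
    if len(t) < 2:
        raise ValueError("trace too short to segment")
    dt = float(np.median(np.diff(t)))
    if t[-1] + 1.5 * dt < events[-1].end_s:
        raise ValueError("trace does not cover the schedule's time span")

    if eye == "mean":
        diam = 0.5 * (trace.right_pupil_mm + trace.left_pupil_mm)
        valid = trace.valid_right & trace.valid_left
    elif eye == "right":
        diam, valid = trace.right_pupil_mm, trace.valid_right
    elif eye == "left":
        diam, valid = trace.left_pupil_mm, trace.valid_left
    else:
        raise ValueError(f"eye must be 'mean', 'right' or 'left', got {eye!r}")

    epochs: list[StimEpoch] = []
    for ev in events:
        win = (t >= ev.start_s) & (t < ev.end_s)
        base = (t >= ev.start_s - baseline_window_s) & (t < ev.start_s)
        n_win = int(win.sum())
        frac_invalid = 1.0 if n_win == 0 else float((~valid[win]).sum()) / n_win

        rejected, reason = False, ""
        excluded = drop_first_repetition and ev.repetition_index == 1
        if excluded:
            reason = "adaptation swing (first repetition of level)"

        base_vals = diam[base & valid]
        win_vals = diam[win & valid]
        if frac_invalid > reject_invalid_frac:
            rejected, reason = True, "too many invalid samples in window"
        elif base_vals.size == 0:
            rejected, reason = True, "no valid baseline samples"
        elif win_vals.size == 0:
            rejected, reason = True, "no valid samples in window"

        baseline = float(np.median(base_vals)) if base_vals.size else np.nan
        min_mm = float(np.min(win_vals)) if win_vals.size else np.nan
        amp = max(baseline - min_mm, 0.0) if np.isfinite(baseline) and np.isfinite(min_mm) else np.nan
        epochs.append(
            StimEpoch(
                level_index=ev.level_index,
                repetition_index=ev.repetition_index,
                stimulated_eye=ev.stimulated_eye,
                onset_s=ev.start_s,
                offset_s=ev.end_s,
                baseline_mm=baseline,
                min_mm=min_mm,
                amplitude_mm=amp,
                fraction_invalid=frac_invalid,
                rejected=rejected,
                excluded=excluded,
                reason=reason,
            )
        )
    return epochs


def epoch_amplitude(epoch: StimEpoch) -> float:
    """Constriction amplitude of an accepted epoch: baseline - min, floored at 0."""
    if epoch.rejected:
        raise ValueError(f"epoch rejected: {epoch.reason or 'data quality'}")
    return max(epoch.baseline_mm - epoch.min_mm, 0.0)


def session_usable(epochs: list[StimEpoch],
                   max_rejected_frac: float = DEFAULT_MAX_REJECTED_FRAC) -> bool:
    """A session is usable when data-quality rejections stay below threshold.

    Deliberately excluded adaptation swings do not count against the session;
    the fraction is taken over the analyzable (non-excluded) epochs.
    """
    analyzable = [e for e in epochs if not e.excluded]
    if not analyzable:
        return False
    frac = sum(e.rejected for e in analyzable) / len(analyzable)
    return frac <= max_rejected_frac
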