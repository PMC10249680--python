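"""RAPD scoring by regression of response differences on log-unit attenuation.

For each illumination level, the difference in constriction amplitude between
right-eye and left-eye stimulation (``y``, mm) is plotted against the level's
signed attenuation ``x = a_L - a_R`` (log units).  The amplitude difference is
linear in log-unit attenuation over the tested range, so an ordinary
least-squares line through the level points crosses the x-axis where the two
eyes' responses balance: that x-intercept is the RAPD score.  A positive
score localises the defect to the right eye, a negative one to the left; the
conventional normal range is (-0.3, +0.3) log units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocols import IlluminationLevel, StimulusSchedule, log_attenuation
from .traces import StimEpoch

__all__ = [
    "LevelResponse",
    "RAPDResult",
    "level_responses",
    "rapd_score",
    "classify",
    "levels_from_schedule",
]

DEFAULT_MIN_LEVELS = 3
DEFAULT_MIN_ABS_SLOPE = 0.05  # mm per log unit
NORMAL_RANGE_THRESHOLD = 0.3  # log units


@dataclass(frozen=True)
class LevelResponse:
    """One regression point: a level's signed attenuation and response difference."""

    level_index: int
    x: float  # a_L - a_R, log units
    y: float  # mean amplitude (right stim) - mean amplitude (left stim), mm
    n_right: int
    n_left: int


@dataclass(frozen=True)
class RAPDResult:
    """Fitted RAPD regression: score (x-intercept), line, diagnostics."""

    score: float  # log units; nan when not usable
    slope: float  # mm per log unit
    intercept: float  # mm
    r_squared: float
    n_levels: int
    laterality: str  # "right" | "left" | "none"
    usable: bool


def levels_from_schedule(schedule: StimulusSchedule) -> list[IlluminationLevel]:
    """Reconstruct the illumination levels from a schedule's illuminated events."""
    seen: dict[int, dict[str, float]] = {}
    order: list[int] = []
    for ev in schedule.illuminated_events:
        d = seen.setdefault(ev.level_index, {})
        if ev.level_index not in order:
            order.append(ev.level_index)
        if ev.stimulated_eye == "right":
            d["right"] = ev.right_fraction
        else:
            d["left"] = ev.left_fraction
    levels = []
    for li in order:
        d = seen[li]
        levels.append(IlluminationLevel(li, d.get("right", 1.0), d.get("left", 1.0)))
    return levels


def level_responses(
    epochs: list[StimEpoch],
    levels: list[IlluminationLevel],
    *,
    per_repetition: bool = False,
) -> list[LevelResponse]:
    """Aggregate accepted epochs into regression points, one per level.

    ``y`` is the mean constriction amplitude under right-eye stimulation minus
    the mean under left-eye stimulation; levels lacking accepted epochs on
    either side are omitted.  With ``per_repetition=True`` each repetition
    present on both sides contributes its own point (same x), instead of the
    level mean.
    """
    x_of = {lv.level_index: lv.signed_attenuation_x for lv in levels}
    by_level: dict[int, dict[str, list[StimEpoch]]] = {}
    for ep in epochs:
        if not ep.accepted:
            continue
        if ep.level_index not in x_of:
            raise ValueError(f"epoch level {ep.level_index} not in provided levels")
        by_level.setdefault(ep.level_index, {"right": [], "left": []})[
            ep.stimulated_eye].append(ep)

    responses: list[LevelResponse] = []
    for lv in levels:
        sides = by_level.get(lv.level_index)
        if not sides or not sides["right"] or not sides["left"]:
            continue
        amp = lambda eps: [max(e.baseline_mm - e.min_mm, 0.0) for e in eps]
        if per_repetition:
            right_by_rep = {e.repetition_index: e for e in sides["right"]}
            left_by_rep = {e.repetition_index: e for e in sides["left"]}
            for rep in sorted(set(right_by_rep) & set(left_by_rep)):
                yr = amp([right_by_rep[rep]])[0]
                yl = amp([left_by_rep[rep]])[0]
                responses.append(
                    LevelResponse(lv.level_index, x_of[lv.level_index],
                                  yr - yl, 1, 1))
        else:
            y = float(np.mean(amp(sides["right"])) - np.mean(amp(sides["left"])))
            responses.append(
                LevelResponse(lv.level_index, x_of[lv.level_index], y,
                              len(sides["right"]), len(sides["left"])))
    if not responses:
        raise ValueError("no usable illumination levels")
    return responses


def rapd_score(
    responses: list[LevelResponse],
    min_levels: int = DEFAULT_MIN_LEVELS,
    min_abs_slope: float = DEFAULT_MIN_ABS_SLOPE,
    *,
    weighted: bool = False,
) -> RAPDResult:
    """Fit the regression line and locate its x-intercept, the RAPD score.

    The fit is unweighted OLS over the response points (optionally weighted by
    per-level epoch counts).  When the fitted slope is flatter than
    ``min_abs_slope`` the intercept is numerically unstable and the result is
    flagged unusable (score = nan) rather than reported as a wild value.
    """
    if len(responses) < min_levels:
        raise ValueError(
            f"need at least {min_levels} usable levels, got {len(responses)}")
    x = np.array([r.x for r in responses])
    y = np.array([r.y for r in responses])
    if np.ptp(x) == 0:
        raise ValueError("all levels share one attenuation; regression undefined")

    if weighted:
        w = np.array([r.n_right + r.n_left for r in responses], dtype=float)
    else:
        w = np.ones_like(x)
    wm_x = np.average(x, weights=w)
    wm_y = np.average(y, weights=w)
    sxx = np.sum(w * (x - wm_x) ** 2)
    sxy = np.sum(w * (x - wm_x) * (y - wm_y))
    slope = sxy / sxx
    intercept = wm_y - slope * wm_x

    resid = y - (intercept + slope * x)
    ss_res = float(np.sum(w * resid**2))
    ss_tot = float(np.sum(w * (y - wm_y) ** 2))
    r_squared = 1.0 if ss_tot <= 1e-300 else max(0.0, 1.0 - ss_res / ss_tot)

    usable = abs(slope) >= min_abs_slope
    score = -intercept / slope if usable else float("nan")
    laterality = classify(score) if usable else "none"
    return RAPDResult(
        score=score,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=float(r_squared),
        n_levels=len(responses),
        laterality=laterality,
        usable=usable,
    )


def classify(score: float, threshold: float = NORMAL_RANGE_THRESHOLD) -> str:
    """Laterality of a RAPD score against the normal range.

    ``"right"`` if score > threshold, ``"left"`` if score < -threshold,
    ``"none"`` within the closed normal range [-threshold, threshold].
    """
    if not np.isfinite(score):
        raise ValueError("score is not usable")
    if score > threshold:
        return "right"
    if score < -threshold:
        return "left"
    return "none"
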