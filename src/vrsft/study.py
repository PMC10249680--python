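"""End-to-end study emulation: simulate a cohort, score every session, assess reliability.

`run_study` reproduces the shape of a VR swinging-flashlight test-retest
study: a pool of control subjects with induced deficits is measured twice per
device-protocol condition; every session is preprocessed and scored; per
condition the test/retest scores feed both ICC forms and a Bland-Altman
analysis, and condition pairs sharing subjects are compared the same way
(between-device and between-protocol reliability).  All randomness derives
from one master seed, so a run is reproducible file for file.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import protocols, traces
from .plr_sim import (CohortSession, DeficitSampler, NoiseParams, PupilTrace,
                      SubjectParams, simulate_cohort)
from .protocols import StimulusSchedule, build_protocol, schedule_events
from .reliability import RatingsMatrix, bland_altman, icc_agreement, icc_consistency
from .scoring import RAPDResult, level_responses, levels_from_schedule, rapd_score

__all__ = [
    "Condition",
    "PreprocessingOptions",
    "ScoringOptions",
    "RunConfig",
    "StudyReport",
    "score_trace",
    "run_study",
    "summarize_scores",
    "table4_conditions",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    """One device-protocol arm of the study."""

    device: str  # "vive" | "fove"
    protocol_id: int
    n_subjects: int

    @property
    def label(self) -> str:
        return f"{self.device} protocol {self.protocol_id}"


def table4_conditions() -> list[Condition]:
    """The emulated study's five arms and their completer counts."""
    return [
        Condition("vive", 1, 27),
        Condition("vive", 2, 27),
        Condition("vive", 3, 26),
        Condition("fove", 1, 20),
        Condition("fove", 2, 20),
    ]


@dataclass(frozen=True)
class PreprocessingOptions:
    jump_limit_mm: float = traces.DEFAULT_JUMP_LIMIT_MM
    max_gap_s: float = traces.DEFAULT_MAX_GAP_S
    baseline_window_s: float = traces.DEFAULT_BASELINE_WINDOW_S
    reject_invalid_frac: float = traces.DEFAULT_REJECT_INVALID_FRAC
    max_rejected_frac: float = traces.DEFAULT_MAX_REJECTED_FRAC
    eye: str = "mean"
    drop_first_repetition: bool = True


@dataclass(frozen=True)
class ScoringOptions:
    min_levels: int = 3
    min_abs_slope: float = 0.05
    per_repetition: bool = False
    weighted: bool = False


@dataclass
class RunConfig:
    """Complete, serialisable description of one study emulation run."""

    conditions: list[Condition] = field(default_factory=table4_conditions)
    n_sessions: int = 2
    master_seed: int = 0
    deficit: DeficitSampler = field(default_factory=DeficitSampler)
    session_deficit_sd: float = 0.05  # day-to-day afferent variability, log units
    noise: NoiseParams = field(default_factory=NoiseParams)
    subject: SubjectParams = field(default_factory=SubjectParams)
    preprocessing: PreprocessingOptions = field(default_factory=PreprocessingOptions)
    scoring: ScoringOptions = field(default_factory=ScoringOptions)
    outdir: str | None = None

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        raw["conditions"] = [Condition(**c) for c in raw.get("conditions", [])]
        for key, typ in (("deficit", DeficitSampler), ("noise", NoiseParams),
                         ("subject", SubjectParams),
                         ("preprocessing", PreprocessingOptions),
                         ("scoring", ScoringOptions)):
            if key in raw and isinstance(raw[key], dict):
                if key == "noise" and "blink_dur_range_s" in raw[key]:
                    raw[key]["blink_dur_range_s"] = tuple(raw[key]["blink_dur_range_s"])
                raw[key] = typ(**raw[key])
        return cls(**raw)


def score_trace(
    trace: PupilTrace,
    schedule: StimulusSchedule,
    pre: PreprocessingOptions = PreprocessingOptions(),
    opts: ScoringOptions = ScoringOptions(),
) -> tuple[RAPDResult, dict]:
    """Preprocess and score one session; returns the result and QC counts.

    An unusable session (too many rejected epochs, too few usable levels, or a
    degenerate regression) yields ``usable=False`` with a nan score instead of
    raising.
    """
    masked = traces.mask_invalid(trace, pre.jump_limit_mm)
    repaired = traces.interpolate_gaps(masked, pre.max_gap_s)
    epochs = traces.segment_epochs(
        repaired, schedule,
        baseline_window_s=pre.baseline_window_s,
        reject_invalid_frac=pre.reject_invalid_frac,
        eye=pre.eye,
        drop_first_repetition=pre.drop_first_repetition,
    )
    qc = {
        "epochs_total": len(epochs),
        "epochs_rejected": sum(e.rejected for e in epochs),
        "epochs_excluded": sum(e.excluded for e in epochs),
        "levels_used": 0,
        "session_usable": traces.session_usable(epochs, pre.max_rejected_frac),
    }
    unusable = RAPDResult(float("nan"), float("nan"), float("nan"),
                          float("nan"), 0, "none", False)
    if not qc["session_usable"]:
        return unusable, qc
    try:
        responses = level_responses(
            epochs, levels_from_schedule(schedule),
            per_repetition=opts.per_repetition)
        qc["levels_used"] = len({r.level_index for r in responses})
        result = rapd_score(responses, opts.min_levels, opts.min_abs_slope,
                            weighted=opts.weighted)
    except ValueError as exc:
        logger.info("session unusable at scoring stage: %s", exc)
        qc["session_usable"] = False
        return unusable, qc
    return result, qc


@dataclass
class StudyReport:
    """All tables a study run produces."""

    scores: pd.DataFrame  # one row per subject x session x condition
    reliability: pd.DataFrame  # test-retest ICC + BA rows, one per condition/form
    pair_reliability: pd.DataFrame  # between-condition rows on shared subjects
    ba_points: pd.DataFrame  # Bland-Altman (mean, difference) points
    summary: pd.DataFrame  # per condition/session quartile summaries
    attrition: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(outdir / "scores.csv", index=False, float_format="%.6f")
        self.reliability.to_csv(outdir / "reliability.csv", index=False,
                                float_format="%.6f")
        self.pair_reliability.to_csv(outdir / "pair_reliability.csv", index=False,
                                     float_format="%.6f")
        self.ba_points.to_csv(outdir / "bland_altman_points.csv", index=False,
                              float_format="%.6f")
        self.summary.to_csv(outdir / "summary.csv", index=False, float_format="%.6f")
        with open(outdir / "run_log.txt", "w", encoding="utf-8") as fh:
            for key, val in self.attrition.items():
                fh.write(f"{key}: {val}\n")


def _icc_rows(label: str, matrix: RatingsMatrix) -> list[dict]:
    rows = []
    for res in (icc_consistency(matrix), icc_agreement(matrix)):
        rows.append(
            dict(condition=label, icc_type=res.icc_type, value=res.value,
                 ci_low=res.ci_low, ci_high=res.ci_high, f=res.f_stat,
                 df1=res.df1, df2=res.df2, p=res.p_value, n=res.n, k=res.k))
    return rows


def run_study(config: RunConfig) -> StudyReport:
    """Simulate, score and analyse the whole study; optionally write the tables.

    Subject identities (and their induced deficits) are shared across
    conditions — condition arms use the first ``n_subjects`` of a common pool
    — so between-condition reliability is computed on genuinely paired
    subjects, as in a within-subject multi-device design.
    """
    if not config.conditions:
        raise ValueError("config has no conditions")
    root = np.random.SeedSequence(config.master_seed)
    pool_n = max(c.n_subjects for c in config.conditions)
    deltas = config.deficit.draw(
        np.random.default_rng(root.spawn(1)[0]), pool_n)
    cond_seeds = np.random.default_rng(root.spawn(1)[0]).integers(
        0, 2**31 - 1, size=len(config.conditions))

    score_rows: list[dict] = []
    attrition: dict = {"sessions_simulated": 0, "sessions_unusable": 0,
                       "epochs_total": 0, "epochs_rejected": 0,
                       "epochs_excluded": 0}
    for cond, seed in zip(config.conditions, cond_seeds):
        spec = build_protocol(cond.protocol_id, cond.device)
        schedule = schedule_events(spec)
        cohort = simulate_cohort(
            cond.n_subjects, deltas[: cond.n_subjects], schedule, config.noise,
            config.n_sessions, int(seed),
            subject_template=config.subject,
            session_deficit_sd=config.session_deficit_sd,
        )
        for sess in cohort:
            result, qc = score_trace(sess.trace, schedule,
                                     config.preprocessing, config.scoring)
            attrition["sessions_simulated"] += 1
            attrition["sessions_unusable"] += int(not qc["session_usable"])
            for key in ("epochs_total", "epochs_rejected", "epochs_excluded"):
                attrition[key] += qc[key]
            score_rows.append(
                dict(subject_id=sess.subject_id, session_id=sess.session_id,
                     device=cond.device, protocol=cond.protocol_id,
                     condition=cond.label, true_delta=sess.true_delta,
                     score=result.score, slope=result.slope,
                     intercept=result.intercept, r_squared=result.r_squared,
                     n_levels=result.n_levels, laterality=result.laterality,
                     usable=result.usable))
    scores = pd.DataFrame(score_rows)

    # test-retest reliability per condition
    rel_rows: list[dict] = []
    ba_rows: list[dict] = []
    dropped_subjects = 0
    for cond in config.conditions:
        sub = scores[scores["condition"] == cond.label]
        matrix = RatingsMatrix.from_long(sub)
        dropped_subjects += matrix.n_dropped
        rel_rows.extend(_icc_rows(cond.label, matrix))
        ba = bland_altman(matrix.values[:, 0], matrix.values[:, 1])
        rel_rows.append(
            dict(condition=cond.label, icc_type="bland_altman", value=ba.bias,
                 ci_low=ba.bias_ci_low, ci_high=ba.bias_ci_high,
                 f=float("nan"), df1=float("nan"), df2=float("nan"),
                 p=float("nan"), n=ba.n, k=config.n_sessions))
        for sid, (mean, diff) in zip(matrix.subject_ids, ba.pairs):
            ba_rows.append(dict(condition=cond.label, subject_id=sid,
                                mean=mean, difference=diff))
    attrition["subjects_dropped_listwise"] = dropped_subjects

    # between-condition reliability on shared subjects (session 1 scores)
    pair_rows: list[dict] = []
    first = scores[scores["session_id"] == 1]
    for i, ca in enumerate(config.conditions):
        for cb in config.conditions[i + 1:]:
            merged = first[first["condition"] == ca.label].merge(
                first[first["condition"] == cb.label],
                on="subject_id", suffixes=("_a", "_b"))
            merged = merged.dropna(subset=["score_a", "score_b"])
            if len(merged) < 3:
                continue
            mat = RatingsMatrix(
                merged[["score_a", "score_b"]].to_numpy(float),
                merged["subject_id"].tolist(), [ca.label, cb.label])
            for row in _icc_rows(f"{ca.label} vs {cb.label}", mat):
                pair_rows.append(row)
    pair_reliability = pd.DataFrame(pair_rows)

    summary = summarize_scores(scores)
    report = StudyReport(
        scores=scores,
        reliability=pd.DataFrame(rel_rows),
        pair_reliability=pair_reliability,
        ba_points=pd.DataFrame(ba_rows),
        summary=summary,
        attrition=attrition,
    )
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.write(outdir)
        config.to_yaml(outdir / "config.yaml")
    return report


def summarize_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary plus 1.5-IQR outliers per condition and session."""
    rows = []
    for (cond, sess), grp in scores.groupby(["condition", "session_id"]):
        vals = grp["score"].dropna().to_numpy(float)
        if vals.size == 0:
            logger.warning("condition %r session %s has no usable scores; skipped",
                           cond, sess)
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        out = vals[(vals < q1 - 1.5 * iqr) | (vals > q3 + 1.5 * iqr)]
        rows.append(
            dict(condition=cond, session_id=sess, n=vals.size,
                 min=vals.min(), q1=q1, median=med, q3=q3, max=vals.max(),
                 n_outliers=out.size,
                 outliers=";".join(f"{v:.4f}" for v in sorted(out))))
    return pd.DataFrame(rows)
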