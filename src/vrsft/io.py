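"""Session CSV dialect: the eye-tracker export schema and its round trip.

A session file is a plain UTF-8, comma-delimited, LF-terminated CSV with one
row per sample and an exact, ordered header::

    time_s,right_intensity_frac,left_intensity_frac,right_pupil_mm,
    left_pupil_mm,right_gaze_x,right_gaze_y,left_gaze_x,left_gaze_y,
    valid_right,valid_left

Stimulus intensity is stored as a fraction of the device baseline so traces
are portable between headsets.  The two validity columns are 0/1; files
lacking them are accepted, with validity inferred from the diameter (positive
and physiologically plausible).  Floats are written at six decimals, so
``write_session(read_session(f)) == f`` byte for byte for files this module
wrote.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .plr_sim import PupilTrace

__all__ = ["SESSION_COLUMNS", "read_session", "write_session"]

logger = logging.getLogger(__name__)

SESSION_COLUMNS = [
    "time_s",
    "right_intensity_frac",
    "left_intensity_frac",
    "right_pupil_mm",
    "left_pupil_mm",
    "right_gaze_x",
    "right_gaze_y",
    "left_gaze_x",
    "left_gaze_y",
    "valid_right",
    "valid_left",
]

_FLOAT_COLUMNS = SESSION_COLUMNS[:9]


def write_session(trace: PupilTrace, path) -> None:
    """Write a trace in the session CSV dialect (6-decimal floats, 0/1 flags)."""
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "right_intensity_frac": trace.right_intensity_frac,
            "left_intensity_frac": trace.left_intensity_frac,
            "right_pupil_mm": trace.right_pupil_mm,
            "left_pupil_mm": trace.left_pupil_mm,
            "right_gaze_x": trace.right_gaze_x,
            "right_gaze_y": trace.right_gaze_y,
            "left_gaze_x": trace.left_gaze_x,
            "left_gaze_y": trace.left_gaze_y,
            "valid_right": trace.valid_right.astype(int),
            "valid_left": trace.valid_left.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def _check_header(columns: list[str]) -> bool:
    """Validate the header; returns True when validity columns are present."""
    expected_full = SESSION_COLUMNS
    expected_short = SESSION_COLUMNS[:9]
    for want in (expected_full, expected_short):
        if len(columns) == len(want):
            for got, exp in zip(columns, want):
                if got != exp:
                    raise ValueError(
                        f"session CSV header mismatch: expected column "
                        f"{exp!r}, found {got!r}")
            return want is expected_full
    raise ValueError(
        f"session CSV must have {len(expected_full)} (or {len(expected_short)}"
        f" without validity) columns, found {len(columns)}: {columns}")


def read_session(path) -> PupilTrace:
    """Parse a session CSV into a :class:`~vrsft.plr_sim.PupilTrace`.

    Malformed (non-numeric) rows are dropped and counted in the log.  A
    non-monotone timestamp column is an error.  Missing validity columns are
    reconstructed from the diameters (valid iff in (1, 10) mm).
    """
    df = pd.read_csv(path)
    has_valid = _check_header(list(df.columns))

    numeric = df.apply(pd.to_numeric, errors="coerce")
    malformed = numeric[_FLOAT_COLUMNS].isna().any(axis=1)
    if malformed.any():
        logger.warning("%s: dropped %d malformed row(s)", path, int(malformed.sum()))
        numeric = numeric[~malformed]
    if len(numeric) == 0:
        raise ValueError(f"{path}: no parseable samples")

    t = numeric["time_s"].to_numpy(dtype=float)
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: time_s must be strictly increasing")

    if has_valid:
        valid_r = numeric["valid_right"].to_numpy(dtype=float) != 0
        valid_l = numeric["valid_left"].to_numpy(dtype=float) != 0
    else:
        rp = numeric["right_pupil_mm"].to_numpy(dtype=float)
        lp = numeric["left_pupil_mm"].to_numpy(dtype=float)
        valid_r = (rp > 1.0) & (rp < 10.0)
        valid_l = (lp > 1.0) & (lp < 10.0)

    return PupilTrace(
        time_s=t,
        right_intensity_frac=numeric["right_intensity_frac"].to_numpy(float),
        left_intensity_frac=numeric["left_intensity_frac"].to_numpy(float),
        right_pupil_mm=numeric["right_pupil_mm"].to_numpy(float),
        left_pupil_mm=numeric["left_pupil_mm"].to_numpy(float),
        right_gaze_x=numeric["right_gaze_x"].to_numpy(float),
        right_gaze_y=numeric["right_gaze_y"].to_numpy(float),
        left_gaze_x=numeric["left_gaze_x"].to_numpy(float),
        left_gaze_y=numeric["left_gaze_y"].to_numpy(float),
        valid_right=valid_r,
        valid_left=valid_l,
    )
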