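"""Agreement statistics for repeated RAPD measurements.

Implements the two-way mixed-effects, single-measurement intraclass
correlation coefficients of McGraw & Wong — ICC(C,1), which ignores a fixed
session offset, and ICC(A,1), which penalises it — from the two-way ANOVA
mean squares, with 95% confidence intervals (exact F pivot for consistency,
Satterthwaite-df approximation for absolute agreement) and the F test of
ICC = 0.  Bland–Altman analysis summarises test–retest agreement as the mean
difference (bias), the 1.96·SD limits of agreement, and a t-based CI of the
bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "BAResult",
    "anova_mean_squares",
    "icc_consistency",
    "icc_agreement",
    "interpret_icc",
    "bland_altman",
]

LOA_MULTIPLIER = 1.96


@dataclass
class RatingsMatrix:
    """n subjects x k repeated measurements, complete cases only."""

    values: np.ndarray
    subject_ids: list[str]
    measurement_labels: list[str]
    n_dropped: int = 0  # incomplete rows removed on construction

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ratings must be a 2-D (subjects x measurements) array")
        n, k = self.values.shape
        if n < 3 or k < 2:
            raise ValueError(f"need n >= 3 subjects and k >= 2 measurements, got {n}x{k}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ratings matrix must be complete (no NaN); "
                             "use from_long for listwise deletion")

    @classmethod
    def from_array(cls, values) -> "RatingsMatrix":
        values = np.asarray(values, dtype=float)
        complete = np.all(np.isfinite(values), axis=1)
        kept = values[complete]
        n, k = values.shape
        return cls(
            kept,
            [f"S{i + 1}" for i in np.flatnonzero(complete)],
            [f"M{j + 1}" for j in range(k)],
            n_dropped=int(n - kept.shape[0]),
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, subject_col: str = "subject_id",
                  measurement_col: str = "session_id",
                  value_col: str = "score") -> "RatingsMatrix":
        """Pivot a long results table; rows with any missing cell are dropped."""
        wide = df.pivot_table(index=subject_col, columns=measurement_col,
                              values=value_col, aggfunc="first")
        complete = wide.dropna()
        return cls(
            complete.to_numpy(dtype=float),
            [str(s) for s in complete.index],
            [str(c) for c in complete.columns],
            n_dropped=int(len(wide) - len(complete)),
        )


@dataclass(frozen=True)
class ICCResult:
    icc_type: str  # "consistency" | "agreement"
    value: float
    ci_low: float
    ci_high: float
    f_stat: float
    df1: float
    df2: float
    p_value: float
    n: int
    k: int
    ms_rows: float
    ms_cols: float
    ms_error: float
    defined: bool = True


@dataclass(frozen=True)
class BAResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    bias_ci_low: float
    bias_ci_high: float
    pairs: tuple[tuple[float, float], ...]  # (mean, difference) per subject
    n: int


def _as_matrix(matrix) -> RatingsMatrix:
    if isinstance(matrix, RatingsMatrix):
        return matrix
    return RatingsMatrix.from_array(np.asarray(matrix, dtype=float))


def anova_mean_squares(matrix) -> tuple[float, float, float]:
    """Two-way ANOVA decomposition without replication.

    Returns ``(ms_rows, ms_cols, ms_error)`` on ``n-1``, ``k-1`` and
    ``(n-1)(k-1)`` degrees of freedom; the three sums of squares add up to the
    total about the grand mean.
    """
    m = _as_matrix(matrix)
    x = m.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_error = max(ss_error, 0.0) / ((n - 1) * (k - 1))
    return float(ms_rows), float(ms_cols), float(ms_error)


def _f_and_p(ms_rows: float, ms_error: float, df1: float, df2: float):
    if ms_error == 0.0:
        return math.inf, 0.0 if ms_rows > 0 else 1.0
    f = ms_rows / ms_error
    return f, float(stats.f.sf(f, df1, df2))


def icc_consistency(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(C,1): single-measurement consistency.

    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E)`` — invariant to a fixed offset
    between measurement occasions.  The 95% CI uses the exact F pivot.
    """
    m = _as_matrix(matrix)
    n, k = m.values.shape
    ms_rows, ms_cols, ms_error = anova_mean_squares(m)
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)

    denom = ms_rows + (k - 1) * ms_error
    if denom == 0.0:
        return ICCResult("consistency", math.nan, math.nan, math.nan,
                         math.nan, df1, df2, math.nan, n, k,
                         ms_rows, ms_cols, ms_error, defined=False)
    value = (ms_rows - ms_error) / denom
    f, p = _f_and_p(ms_rows, ms_error, df1, df2)
    if math.isinf(f):
        ci_low, ci_high = value, 1.0
    else:
        fl = f / stats.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * stats.f.ppf(1 - alpha / 2, df2, df1)
        ci_low = (fl - 1.0) / (fl + k - 1.0)
        ci_high = (fu - 1.0) / (fu + k - 1.0)
    return ICCResult("consistency", float(value), float(ci_low), float(ci_high),
                     f, df1, df2, p, n, k, ms_rows, ms_cols, ms_error)


def icc_agreement(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1): single-measurement absolute agreement.

    ``(MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))`` — a fixed
    offset between occasions lowers it.  The 95% CI uses the McGraw–Wong
    Satterthwaite-df approximation; the F test is against ICC = 0 as for
    consistency.
    """
    m = _as_matrix(matrix)
    n, k = m.values.shape
    ms_rows, ms_cols, ms_error = anova_mean_squares(m)
    df1, df2 = n - 1.0, (n - 1.0) * (k - 1.0)

    denom = ms_rows + (k - 1) * ms_error + (k / n) * (ms_cols - ms_error)
    if denom == 0.0:
        return ICCResult("agreement", math.nan, math.nan, math.nan,
                         math.nan, df1, df2, math.nan, n, k,
                         ms_rows, ms_cols, ms_error, defined=False)
    value = (ms_rows - ms_error) / denom
    f, p = _f_and_p(ms_rows, ms_error, df1, df2)

    if ms_error == 0.0 and ms_cols == 0.0:
        ci_low, ci_high = value, 1.0
    else:
        a = k * value / (n * (1.0 - value)) if value < 1.0 else math.inf
        if math.isinf(a):
            ci_low, ci_high = value, 1.0
        else:
            b = 1.0 + k * value * (n - 1.0) / (n * (1.0 - value))
            num = (a * ms_cols + b * ms_error) ** 2
            den = ((a * ms_cols) ** 2 / (k - 1.0)
                   + (b * ms_error) ** 2 / ((n - 1.0) * (k - 1.0)))
            v = num / den if den > 0 else 1.0
            f_lo = stats.f.ppf(1 - alpha / 2, n - 1.0, v)
            f_hi = stats.f.ppf(1 - alpha / 2, v, n - 1.0)
            common = k * ms_cols + (k * n - k - n) * ms_error
            ci_low = n * (ms_rows - f_lo * ms_error) / (f_lo * common + n * ms_rows)
            ci_high = n * (f_hi * ms_rows - ms_error) / (common + n * f_hi * ms_rows)
    return ICCResult("agreement", float(value), float(ci_low), float(ci_high),
                     f, df1, df2, p, n, k, ms_rows, ms_cols, ms_error)


_CICCHETTI = [(0.75, "excellent"), (0.6, "good"), (0.4, "fair"), (-math.inf, "poor")]
_KOO_LI = [(0.9, "excellent"), (0.75, "good"), (0.5, "moderate"), (-math.inf, "poor")]


def interpret_icc(value: float, scheme: str = "koo_li") -> str:
    """Qualitative label for an ICC under a published interpretation scale.

    ``"cicchetti"``: poor < 0.4 <= fair < 0.6 <= good < 0.75 <= excellent;
    ``"koo_li"``: poor < 0.5 <= moderate < 0.75 <= good < 0.9 <= excellent.
    Lower bin edges are inclusive.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must lie in [-1, 1], got {value}")
    table = {"cicchetti": _CICCHETTI, "koo_li": _KOO_LI}.get(scheme)
    if table is None:
        raise ValueError(f"unknown scheme {scheme!r}; expected 'cicchetti' or 'koo_li'")
    for edge, label in table:
        if value >= edge:
            return label
    raise AssertionError("unreachable")


def bland_altman(t1: Sequence[float], t2: Sequence[float]) -> BAResult:
    """Bland–Altman agreement of paired test/retest scores.

    Differences are ``t1 - t2``; bias is their mean, the limits of agreement
    are bias ± 1.96 × SD of the differences (sample SD, n-1), and the bias CI
    is t-based: bias ± t(0.975, n-1) · SD / sqrt(n).
    """
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if t1.shape != t2.shape or t1.ndim != 1:
        raise ValueError("t1 and t2 must be 1-D and the same length")
    n = len(t1)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diff = t1 - t2
    mean = (t1 + t2) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
    return BAResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        bias_ci_low=bias - half,
        bias_ci_high=bias + half,
        pairs=tuple(zip(mean.tolist(), diff.tolist())),
        n=n,
    )
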