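"""Clinical-score trajectory analytics.

Scores live on the half-integer grid 0-6 (0 = no signs ... 6 = death, death
absorbing).  Per animal the module computes the cumulative disease index
(CDI: the sum of the daily scores up to a cut-off day), the maximum score,
the onset day and a severity class; group vectors can be screened for
aberrant values with Dixon's Q test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoreValidationError",
    "SeverityBands",
    "TrajectorySummary",
    "DixonResult",
    "validate_scores",
    "cumulative_disease_index",
    "summarize_trajectory",
    "summarize_animals",
    "dixon_filter",
]

_HALF_GRID = np.arange(0.0, 6.5, 0.5)


class ScoreValidationError(ValueError):
    pass


def validate_scores(records: pd.DataFrame) -> pd.DataFrame:
    """Validate a long score table (animal_id, group, day, score).

    Enforces the half-integer 0-6 grid, unique strictly increasing days per
    animal, and death (score 6) as an absorbing state.  Violations are
    reported with their row numbers.
    """
    df = records.reset_index(drop=True)
    problems = []
    off_grid = ~df["score"].isin(_HALF_GRID)
    for i in df.index[off_grid]:
        problems.append(f"row {i}: score {df.at[i, 'score']} is off the "
                        "half-integer 0-6 grid")
    for animal, sub in df.groupby("animal_id"):
        dup = sub["day"].duplicated()
        for i in sub.index[dup]:
            problems.append(f"row {i}: duplicate day {sub.at[i, 'day']} "
                            f"for animal {animal}")
        ordered = sub.sort_values("day")
        dead = (ordered["score"] == 6.0).to_numpy()
        if dead.any():
            after = np.flatnonzero(dead)[0] + 1
            for i in ordered.index[after:]:
                problems.append(f"row {i}: observation after death (score 6) "
                                f"for animal {animal}")
    if problems:
        raise ScoreValidationError("; ".join(problems))
    return df.sort_values(["animal_id", "day"]).reset_index(drop=True)


def _trajectory_series(traj) -> pd.Series:
    if isinstance(traj, pd.DataFrame):
        traj = traj.set_index("day")["score"]
    return traj.sort_index()


def cumulative_disease_index(
    traj, end_day: int, *, carry_forward: bool = False,
) -> float:
    """CDI: sum of the daily clinical scores up to and including end_day.

    By default only observed days are summed; with ``carry_forward`` missing
    days take the last observed score (death carries a 6 forward).
    """
    s = _trajectory_series(traj)
    if end_day < s.index.min():
        raise ValueError("end_day precedes the first observation")
    s = s[s.index <= end_day]
    if carry_forward:
        full = np.arange(s.index.min(), end_day + 1)
        s = s.reindex(full).ffill()
    return float(s.sum())


@dataclass(frozen=True)
class SeverityBands:
    """Severity classes from the maximum score: none (0), mild (<= mild_max),
    severe (>= severe_min), moderate in between."""

    mild_max: float = 2.0
    severe_min: float = 3.5

    def classify(self, max_score: float) -> str:
        if max_score == 0.0:
            return "none"
        if max_score <= self.mild_max:
            return "mild"
        if max_score >= self.severe_min:
            return "severe"
        return "moderate"


@dataclass(frozen=True)
class TrajectorySummary:
    cdi: float
    max_score: float
    severity_class: str
    onset_day: int | None


def summarize_trajectory(
    traj,
    *,
    end_day: int | None = None,
    bands: SeverityBands = SeverityBands(),
    carry_forward: bool = False,
) -> TrajectorySummary:
    """Maximum score, onset (first day with score > 0), severity class and
    CDI of one validated trajectory."""
    s = _trajectory_series(traj)
    if end_day is None:
        end_day = int(s.index.max())
    cdi = cumulative_disease_index(s, end_day, carry_forward=carry_forward)
    window = s[s.index <= end_day]
    max_score = float(window.max())
    nonzero = window[window > 0]
    onset = int(nonzero.index[0]) if len(nonzero) else None
    return TrajectorySummary(cdi=cdi, max_score=max_score,
                             severity_class=bands.classify(max_score),
                             onset_day=onset)


def summarize_animals(
    scores: pd.DataFrame,
    *,
    end_day: int | None = None,
    bands: SeverityBands = SeverityBands(),
    carry_forward: bool = False,
) -> pd.DataFrame:
    """Per-animal summary table for a validated long score table."""
    rows = []
    for (animal, group), sub in scores.groupby(["animal_id", "group"]):
        summ = summarize_trajectory(sub[["day", "score"]], end_day=end_day,
                                    bands=bands, carry_forward=carry_forward)
        rows.append((animal, group, summ.cdi, summ.max_score,
                     summ.severity_class, summ.onset_day))
    return pd.DataFrame(rows, columns=[
        "animal_id", "group", "cdi", "max_score", "severity", "onset_day"])


# ---------------------------------------------------------------------------
# Dixon's Q test

# Rorabacher (1991), two-sided critical values at the 95% confidence level,
# for the n-dependent ratio scheme r10 (n<=7), r11 (8-10), r21 (11-13),
# r22 (14-30).
_DIXON_Q95 = {
    3: 0.970, 4: 0.829, 5: 0.710, 6: 0.625, 7: 0.568,
    8: 0.608, 9: 0.564, 10: 0.530,
    11: 0.619, 12: 0.583, 13: 0.557,
    14: 0.670, 15: 0.637, 16: 0.611, 17: 0.589, 18: 0.571, 19: 0.555,
    20: 0.542, 21: 0.530, 22: 0.520, 23: 0.510, 24: 0.502, 25: 0.495,
    26: 0.489, 27: 0.483, 28: 0.477, 29: 0.472, 30: 0.467,
}


def _dixon_ratios(x: np.ndarray) -> tuple[float, float, str]:
    """(Q_low, Q_high, variant) for a sorted sample."""
    n = x.size
    if n <= 7:
        variant = "r10"
        q_hi = (x[-1] - x[-2]) / (x[-1] - x[0])
        q_lo = (x[1] - x[0]) / (x[-1] - x[0])
    elif n <= 10:
        variant = "r11"
        q_hi = _safe_ratio(x[-1] - x[-2], x[-1] - x[1])
        q_lo = _safe_ratio(x[1] - x[0], x[-2] - x[0])
    elif n <= 13:
        variant = "r21"
        q_hi = _safe_ratio(x[-1] - x[-3], x[-1] - x[1])
        q_lo = _safe_ratio(x[2] - x[0], x[-2] - x[0])
    else:
        variant = "r22"
        q_hi = _safe_ratio(x[-1] - x[-3], x[-1] - x[2])
        q_lo = _safe_ratio(x[2] - x[0], x[-3] - x[0])
    return q_lo, q_hi, variant


def _safe_ratio(num: float, den: float) -> float:
    return 0.0 if den == 0.0 else num / den


@dataclass(frozen=True)
class DixonResult:
    kept: np.ndarray
    removed: float | None
    q: float
    q_crit: float
    variant: str


def dixon_filter(values, alpha: float = 0.05) -> DixonResult:
    """Dixon's Q screen of one group vector (3 <= n <= 30), single pass.

    The larger of the low-end and high-end gap ratios is compared with the
    two-sided 95% critical value; at most one value is removed.  A constant
    vector (zero range) is returned untouched.  Only alpha = 0.05 is
    supported (the embedded table).
    """
    if alpha != 0.05:
        raise NotImplementedError(
            "only the two-sided 95% Dixon table is embedded")
    x = np.sort(np.asarray(values, dtype=float))
    if not 3 <= x.size <= 30:
        raise ValueError("Dixon's test requires 3 <= n <= 30")
    crit = _DIXON_Q95[x.size]
    if x[-1] == x[0]:
        return DixonResult(kept=x, removed=None, q=0.0, q_crit=crit,
                           variant="degenerate")
    q_lo, q_hi, variant = _dixon_ratios(x)
    if q_hi >= q_lo:
        q, suspect_idx = q_hi, x.size - 1
    else:
        q, suspect_idx = q_lo, 0
    if q > crit:
        return DixonResult(kept=np.delete(x, suspect_idx),
                           removed=float(x[suspect_idx]),
                           q=float(q), q_crit=crit, variant=variant)
    return DixonResult(kept=x, removed=None, q=float(q), q_crit=crit,
                       variant=variant)
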