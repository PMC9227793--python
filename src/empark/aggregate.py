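"""Per-day score rows, rolling summaries, score bands and correlation.

The daily summary is one row per calendar day with the six 0–100 scores —
medication, sleep, bradykinesia, dyskinesia, meal, exercise — plus the
overall day score (the VAS item) and the eight re-coded quality-of-life
items.  Missing data stay missing; nothing is imputed.  Scores are banded
good (>70, green), average (30–70, gray) and bad (<30, orange).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import lifestyle, medication, motor, sleep
from .config import EngineConfig
from .events import Scenario, partition_by_day
from .lifestyle import DayExerciseResult, DayMealResult, DayQoLResult
from .medication import DayMedicationResult
from .motor import DayMotorResult
from .sleep import SleepComponents

#: score columns of the daily summary, in output order
SCORE_COLUMNS = (
    "medication",
    "sleep",
    "bradykinesia",
    "dyskinesia",
    "meal",
    "exercise",
    "overall_day",
)
QOL_COLUMNS = tuple(f"qol_q{k}" for k in range(1, 9))
ALL_COLUMNS = SCORE_COLUMNS + QOL_COLUMNS

GOOD_THRESHOLD = 70.0
BAD_THRESHOLD = 30.0


class InsufficientDataError(ValueError):
    """Fewer complete pairs than required for a correlation."""


@dataclass(frozen=True, slots=True)
class ScoreBand:
    band: str  # good | average | bad
    color: str  # green | gray | orange


_BANDS = {
    "good": ScoreBand("good", "green"),
    "average": ScoreBand("average", "gray"),
    "bad": ScoreBand("bad", "orange"),
}


@dataclass(frozen=True, slots=True)
class DailyScores:
    """One calendar-day row of the daily summary."""

    date: date
    medication: float | None = None
    sleep: float | None = None
    bradykinesia: float | None = None
    dyskinesia: float | None = None
    meal: float | None = None
    exercise: float | None = None
    overall_day: float | None = None
    qol_items: tuple[int, ...] | None = None  # 8 items, 0 worst .. 2 best

    def __post_init__(self) -> None:
        for name in SCORE_COLUMNS:
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} score {v} outside [0, 100] on {self.date}")

    def as_row(self) -> dict:
        row: dict = {"date": self.date}
        for name in SCORE_COLUMNS:
            row[name] = getattr(self, name)
        items = self.qol_items if self.qol_items is not None else (None,) * 8
        for col, v in zip(QOL_COLUMNS, items):
            row[col] = v
        return row


@dataclass(frozen=True, slots=True)
class CorrelationReport:
    x: str
    y: str
    lag_days: int
    method: str
    coefficient: float
    p_value: float
    n: int
    start: date
    end: date


def assemble_daily_summary(
    day: date,
    med: DayMedicationResult | None = None,
    slp: SleepComponents | None = None,
    mot: DayMotorResult | None = None,
    meal: DayMealResult | None = None,
    exercise: DayExerciseResult | None = None,
    qol: DayQoLResult | None = None,
) -> DailyScores:
    """Combine per-stream day results into one row; dates must agree."""
    for r in (med, mot, meal, exercise, qol):
        if r is not None and r.date is not None and r.date != day:
            raise ValueError(f"date mismatch: row is {day}, component is {r.date}")
    return DailyScores(
        date=day,
        medication=med.daily_score if med is not None else None,
        sleep=slp.sleep_score if slp is not None else None,
        bradykinesia=mot.bradykinesia_score if mot is not None else None,
        dyskinesia=mot.dyskinesia_score if mot is not None else None,
        meal=meal.meal_score if meal is not None else None,
        exercise=exercise.exercise_score if exercise is not None else None,
        overall_day=qol.overall_day_score if qol is not None else None,
        qol_items=qol.item_scores if qol is not None else None,
    )


def score_scenario(
    scenario: Scenario,
    config: EngineConfig | None = None,
    include_motor_average: bool = False,
) -> pd.DataFrame:
    """Run the full daily scoring pipeline over a scenario.

    Returns one row per calendar day (continuous axis from first to last
    event), columns ``date, medication, sleep, bradykinesia, dyskinesia,
    meal, exercise, overall_day, qol_q1..qol_q8``; missing values are NaN.
    When a wake day carries more than one sleep episode, the episode with
    the most time in bed is scored.  ``include_motor_average`` adds the
    legacy averaged ``motor`` column.
    """
    cfg = config or EngineConfig()
    parts = partition_by_day(
        scenario,
        night_chain_gap_h=cfg.night_chain_gap_h,
        night_start_after_h=cfg.night_start_after_h,
        night_start_before_h=cfg.night_start_before_h,
    )
    rows = []
    for day in sorted(parts):
        sl = parts[day]
        med = medication.score_day(sl.planned_doses, sl.taken_doses, cfg, day) \
            if (sl.planned_doses or sl.taken_doses) else None
        slp = None
        if sl.nights:
            chain = max(sl.nights, key=lambda c: sum(iv.duration_h for iv in c))
            slp = sleep.score_night(sleep.night_from_chain(chain, cfg))
        mot = motor.daily_motor_scores(sl.motor_samples, day) if sl.motor_samples else None
        meal = lifestyle.meal_timing_score(sl.meals, sl.taken_doses, cfg, day) \
            if sl.meals else None
        exc = lifestyle.physical_activity_score(sl.exercise, scenario.patient_target, day) \
            if sl.exercise else None
        qol = lifestyle.qol_daily(sl.qol) if sl.qol is not None else None
        rows.append(assemble_daily_summary(day, med, slp, mot, meal, exc, qol).as_row())

    df = pd.DataFrame(rows, columns=["date"] + list(ALL_COLUMNS))
    df["date"] = pd.to_datetime(df["date"]) if len(df) else pd.to_datetime(df.get("date", []))
    for c in ALL_COLUMNS:
        df[c] = pd.to_numeric(df[c])
    if include_motor_average:
        df["motor"] = df[["bradykinesia", "dyskinesia"]].mean(axis=1)
    return df


def rolling_summary(df: pd.DataFrame, window_days: int = 14) -> pd.Series:
    """Per-score means over the last ``window_days`` rows, skipping missing values."""
    if window_days < 1:
        raise ValueError("window_days must be >= 1")
    cols = [c for c in df.columns if c in SCORE_COLUMNS or c == "motor"]
    tail = df.sort_values("date").tail(window_days)
    return tail[cols].mean(skipna=True)


def classify_score(value: float | None) -> ScoreBand | None:
    """Band a 0–100 score: >70 good/green, 30–70 average/gray, <30 bad/orange."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if not (0.0 <= value <= 100.0):
        raise ValueError(f"score {value} outside [0, 100]")
    if value > GOOD_THRESHOLD:
        return _BANDS["good"]
    if value < BAD_THRESHOLD:
        return _BANDS["bad"]
    return _BANDS["average"]


def band_report(means: Mapping[str, float]) -> dict[str, dict]:
    """Band each score of a rolling summary; missing scores band as None."""
    out: dict[str, dict] = {}
    for name, v in means.items():
        band = classify_score(None if pd.isna(v) else float(v))
        out[name] = {
            "mean": None if pd.isna(v) else float(v),
            "band": band.band if band else None,
            "color": band.color if band else None,
        }
    return out


def correlate_scores(
    df: pd.DataFrame,
    x: str,
    y: str,
    lag_days: int = 0,
    method: str = "pearson",
    min_pairs: int = 3,
) -> CorrelationReport:
    """Correlate two daily scores over pairwise-complete days.

    ``lag_days`` shifts *y* forward: the pair is (x on day d, y on day
    d + lag_days).  Pearson by default; Spearman by flag.
    """
    for name in (x, y):
        if name not in df.columns:
            raise KeyError(f"unknown score {name!r}; available: {sorted(set(df.columns) - {'date'})}")
    d = df.sort_values("date").reset_index(drop=True)
    xs = d[x]
    ys = d[y].shift(-lag_days)
    mask = xs.notna() & ys.notna()
    n = int(mask.sum())
    if n < min_pairs:
        raise InsufficientDataError(
            f"only {n} complete ({x}, {y}) pairs at lag {lag_days}; need >= {min_pairs}"
        )
    xv = xs[mask].to_numpy(dtype=float)
    yv = ys[mask].to_numpy(dtype=float)
    if method == "pearson":
        r, p = stats.pearsonr(xv, yv)
    elif method == "spearman":
        r, p = stats.spearmanr(xv, yv)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    dates = d.loc[mask, "date"]
    return CorrelationReport(
        x=x, y=y, lag_days=lag_days, method=method,
        coefficient=float(r), p_value=float(p), n=n,
        start=dates.iloc[0].date(), end=dates.iloc[-1].date(),
    )


def write_scores_csv(df: pd.DataFrame, path: str) -> None:
    """Write the daily summary with empty cells for missing values."""
    out = df.copy()
    out["date"] = out["date"].dt.date if len(out) else out["date"]
    out.to_csv(path, index=False, na_rep="", float_format="%.6g")


def read_scores_csv(path: str) -> pd.DataFrame:
    """Read a daily summary written by :func:`write_scores_csv`."""
    df = pd.read_csv(path, parse_dates=["date"])
    missing = [c for c in ALL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"scores file {path} lacks columns {missing}")
    return df
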