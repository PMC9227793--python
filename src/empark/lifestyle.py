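"""Self-reported lifestyle scores: meal timing, physical activity, quality of life.

Meal timing
    Levodopa absorption competes with dietary protein, so meals are judged
    against the window 30 minutes before to 60 minutes after each medication
    intake.  By default a meal complies when it *avoids* every such window
    (``meal_window_mode="avoid"``; the ``require`` reading is available).
    Daily score = 100 * NWI / n, NWI the number of compliant meals.

Physical activity
    Each occasion reports a mode weight (1 boxing/dancing/running/swimming,
    2 bicycling/gym, 3 walking) and a duration in minutes.  Daily score =
    min(100, 100 * sum(mode_i * duration_i) / patient_target) against the
    individual patient target.

Quality of life
    Nine daily items: eight three-level items (five EQ-5D-3L dimensions and
    three PDQ-8 items) re-coded so 0 is worst and 2 is best, plus the 0–100
    overall-health visual analogue scale, which serves as the overall day
    score.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Sequence

from .config import EngineConfig
from .events import ExerciseEvent, MealEvent, QoLResponse, TakenDose

#: Table of the nine daily quality-of-life items and their source instruments.
QOL_ITEMS = (
    ("q1", "Mobility", "EQ-5D-3L"),
    ("q2", "Personal care", "EQ-5D-3L"),
    ("q3", "Daily activities", "EQ-5D-3L"),
    ("q4", "Pain or discomfort", "EQ-5D-3L"),
    ("q5", "Worry or depression", "EQ-5D-3L"),
    ("q6", "Concentration difficulties", "PDQ-8"),
    ("q7", "Communication difficulties", "PDQ-8"),
    ("q8", "Painful cramps or spasms in the muscles", "PDQ-8"),
    ("q9", "Overall health", "EQ-5D-3L"),
)


@dataclass(frozen=True, slots=True)
class DayMealResult:
    date: date | None
    nwi: int  # meals within recommendation
    n: int  # reported meals
    meal_score: float | None  # None iff n == 0


@dataclass(frozen=True, slots=True)
class DayExerciseResult:
    date: date | None
    occasions: tuple[ExerciseEvent, ...]
    raw_activity: float  # sum of mode * duration before normalization
    exercise_score: float | None  # None iff no occasions


@dataclass(frozen=True, slots=True)
class DayQoLResult:
    date: date
    item_scores: tuple[int, ...]  # 8 items, 0 worst .. 2 best
    vas: float
    overall_day_score: float  # = vas


def meal_in_any_window(
    meal: MealEvent, intakes: Sequence[TakenDose], config: EngineConfig
) -> bool:
    """True when the meal falls inside [t - before, t + after] of any intake."""
    before = timedelta(minutes=config.meal_window_before_min)
    after = timedelta(minutes=config.meal_window_after_min)
    return any(t.time - before <= meal.time <= t.time + after for t in intakes)


def meal_timing_score(
    meals: Sequence[MealEvent],
    med_intakes: Sequence[TakenDose],
    config: EngineConfig | None = None,
    day: date | None = None,
) -> DayMealResult:
    """Fraction of meals complying with the levodopa meal-timing rule, as 0–100."""
    cfg = config or EngineConfig()
    n = len(meals)
    if n == 0:
        return DayMealResult(date=day, nwi=0, n=0, meal_score=None)
    if cfg.meal_window_mode == "avoid":
        nwi = sum(1 for m in meals if not meal_in_any_window(m, med_intakes, cfg))
    else:
        nwi = sum(1 for m in meals if meal_in_any_window(m, med_intakes, cfg))
    return DayMealResult(date=day, nwi=nwi, n=n, meal_score=100.0 * nwi / n)


def physical_activity_score(
    occasions: Sequence[ExerciseEvent],
    patient_target: float,
    day: date | None = None,
) -> DayExerciseResult:
    """Mode-weighted exercise minutes normalized by the patient target.

    Worked example: occasions (mode 1, 10 min) and (mode 2, 25 min) with
    target 80 give 100 * (10 + 2*25) / 80 = 75.  Scores above the target
    clamp at 100.
    """
    if not (0.0 < patient_target <= 100.0):
        raise ValueError(f"patient_target must be in (0, 100], got {patient_target}")
    if not occasions:
        return DayExerciseResult(date=day, occasions=(), raw_activity=0.0, exercise_score=None)
    raw = sum(o.mode * o.duration_min for o in occasions)
    return DayExerciseResult(
        date=day,
        occasions=tuple(occasions),
        raw_activity=raw,
        exercise_score=min(100.0, 100.0 * raw / patient_target),
    )


def qol_daily(response: QoLResponse) -> DayQoLResult:
    """Re-code the 8 three-level items (level L -> score 3 - L) and pass the VAS through."""
    return DayQoLResult(
        date=response.date,
        item_scores=tuple(3 - lv for lv in response.item_levels),
        vas=response.vas,
        overall_day_score=response.vas,
    )
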