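"""Medication timing-compliance scoring.

The dosing device records both the planned schedule and the delivered
intakes.  Per day, each delivered dose is matched to the nearest planned
occasion, extra doses are classified (replacement within ±30 minutes of a
planned time, otherwise credited at 100), and every scored occasion maps its
timing deviation in minutes to a 0–100 score.  The daily score is the mean
over scored occasions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date
from typing import Sequence

from .config import EngineConfig
from .events import PlannedDose, TakenDose, ValidationError

#: occasion statuses
ON_SCHEDULE = "on-schedule"
REPLACED = "replaced"
MISSED = "missed"
EXTRA_CREDITED = "extra-credited"


@dataclass(frozen=True, slots=True)
class OccasionScore:
    """One scored medication-intake occasion."""

    planned: PlannedDose | None
    matched_taken: TakenDose | None
    deviation_min: float | None
    status: str
    occasion_score: float | None = None

    @property
    def time(self):
        """Reference time of the occasion, for ordering."""
        return self.planned.time if self.planned is not None else self.matched_taken.time


@dataclass(frozen=True, slots=True)
class DayMedicationResult:
    date: date | None
    occasions: tuple[OccasionScore, ...]
    n: int  # number of occasions entering the daily mean
    daily_score: float | None  # None iff n == 0


def _dev_min(a: PlannedDose, b: TakenDose) -> float:
    return abs((b.time - a.time).total_seconds()) / 60.0


def _monotone_matching(small: list, large: list) -> list[tuple[int, int]]:
    """Optimal assignment of every time in ``small`` to a distinct time in
    ``large`` minimizing the total absolute deviation.

    Both lists are sorted, so an optimal assignment never crosses; dynamic
    programming over (matched-in-small, considered-in-large) finds it in
    O(n*m).  Ties are resolved toward the earlier partner in ``large``.
    """
    n, m = len(small), len(large)
    inf = float("inf")
    cost = [[abs((b - a).total_seconds()) / 60.0 for b in large] for a in small]
    dp = [[inf] * (m + 1) for _ in range(n + 1)]
    dp[0] = [0.0] * (m + 1)
    for i in range(1, n + 1):
        for j in range(i, m + 1):
            dp[i][j] = min(dp[i][j - 1], dp[i - 1][j - 1] + cost[i - 1][j - 1])
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0:
        # on equal cost prefer dropping the later candidate in `large`,
        # pushing the match toward the earlier one
        if j > i and dp[i][j] == dp[i][j - 1]:
            j -= 1
        else:
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs


def match_and_classify(
    planned: Sequence[PlannedDose],
    taken: Sequence[TakenDose],
    config: EngineConfig | None = None,
) -> list[OccasionScore]:
    """Match delivered doses to the planned schedule and classify extras.

    Scheduled deliveries are matched to planned occasions by the assignment
    that minimizes the total timing deviation (at most one delivery per
    occasion; on a time line the optimum is non-crossing, found by dynamic
    programming), ties broken toward the earlier delivery.  Extra doses within
    the replacement window of a planned time stand in for that occasion if it
    is otherwise unmatched (status ``replaced``) and are dropped from all
    calculations otherwise; extras outside every window become occasions of
    their own, later credited at 100.  Unmatched planned occasions are
    ``missed``.  Scores are left unset; see :func:`occasion_score`.
    """
    cfg = config or EngineConfig()
    planned = sorted(planned, key=lambda r: r.time)
    for a, b in zip(planned, planned[1:]):
        if (b.time - a.time).total_seconds() < 60.0:
            raise ValidationError(
                f"planned intake times closer than 1 minute: {a.time} and {b.time}"
            )
    scheduled = sorted((t for t in taken if t.source == "scheduled-delivery"),
                       key=lambda r: r.time)
    extras = sorted((t for t in taken if t.source == "extra"), key=lambda r: r.time)

    # minimum-total-deviation matching of scheduled deliveries
    matched_p: dict[int, tuple[int, float]] = {}
    if planned and scheduled:
        if len(planned) <= len(scheduled):
            for pi, ti in _monotone_matching(
                    [p.time for p in planned], [t.time for t in scheduled]):
                matched_p[pi] = (ti, _dev_min(planned[pi], scheduled[ti]))
        else:
            for ti, pi in _monotone_matching(
                    [t.time for t in scheduled], [p.time for p in planned]):
                matched_p[pi] = (ti, _dev_min(planned[pi], scheduled[ti]))

    occasions: list[OccasionScore] = []
    for pi, p in enumerate(planned):
        if pi in matched_p:
            ti, dev = matched_p[pi]
            occasions.append(OccasionScore(planned=p, matched_taken=scheduled[ti],
                                           deviation_min=dev, status=ON_SCHEDULE))
        else:
            occasions.append(OccasionScore(planned=p, matched_taken=None,
                                           deviation_min=None, status=MISSED))

    # extra-dose classification, in time order
    for ex in extras:
        window: list[tuple[float, int]] = []
        for pi, p in enumerate(planned):
            d = _dev_min(p, ex)
            if d <= cfg.replacement_window_min:
                window.append((d, pi))
        if window:
            free = sorted((d, pi) for d, pi in window if occasions[pi].status == MISSED)
            if free:
                d, pi = free[0]
                occasions[pi] = OccasionScore(
                    planned=planned[pi], matched_taken=ex, deviation_min=d, status=REPLACED
                )
            # otherwise: replacement of an already-covered occasion -> omitted entirely
        else:
            occasions.append(OccasionScore(planned=None, matched_taken=ex,
                                           deviation_min=None, status=EXTRA_CREDITED))
    occasions.sort(key=lambda o: o.time)
    return occasions


def occasion_score(occasion: OccasionScore, config: EngineConfig | None = None) -> OccasionScore:
    """Assign the 0–100 score of one classified occasion.

    Deviation maps linearly to the score, reaching 0 at
    ``deviation_max_min`` minutes: ``score = max(0, 100 * (1 - dev/D_max))``.
    Extra-credited occasions score 100, missed occasions 0.
    """
    cfg = config or EngineConfig()
    if occasion.status == EXTRA_CREDITED:
        s = 100.0
    elif occasion.status == MISSED:
        s = 0.0
    elif occasion.status in (ON_SCHEDULE, REPLACED):
        if occasion.status == REPLACED and not cfg.replacement_counts_deviation:
            # occasion is omitted from the daily mean; keep a neutral score
            s = 100.0
        else:
            s = max(0.0, 100.0 * (1.0 - occasion.deviation_min / cfg.deviation_max_min))
    else:  # pragma: no cover - statuses are fixed above
        raise ValueError(f"unknown occasion status {occasion.status!r}")
    return replace(occasion, occasion_score=min(100.0, s))


def daily_medication_score(
    occasions: Sequence[OccasionScore],
    config: EngineConfig | None = None,
    day: date | None = None,
) -> DayMedicationResult:
    """Mean of the occasion scores; missing when the day has no occasion.

    With ``replacement_counts_deviation=False`` replaced occasions are
    omitted from the mean (and from *n*) entirely.
    """
    cfg = config or EngineConfig()
    scored = [o for o in occasions if o.occasion_score is not None]
    if not cfg.replacement_counts_deviation:
        scored = [o for o in scored if o.status != REPLACED]
    n = len(scored)
    score = math.fsum(o.occasion_score for o in scored) / n if n else None
    return DayMedicationResult(date=day, occasions=tuple(occasions), n=n, daily_score=score)


def score_day(
    planned: Sequence[PlannedDose],
    taken: Sequence[TakenDose],
    config: EngineConfig | None = None,
    day: date | None = None,
) -> DayMedicationResult:
    """Full per-day medication pipeline: match, classify, score, average."""
    cfg = config or EngineConfig()
    occ = [occasion_score(o, cfg) for o in match_and_classify(planned, taken, cfg)]
    return daily_medication_score(occ, cfg, day)
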