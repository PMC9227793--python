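"""Daily motor-function scores from 2-minute wrist-sensor samples.

The wrist sensor emits bradykinesia and dyskinesia scores every 2 minutes on
a 0–100 scale (higher = better).  The daily score of each channel is the
arithmetic mean over the day's samples; the two channels are reported
separately.  A day with no samples has missing scores, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date
from typing import Sequence

from .events import MotorSample


@dataclass(frozen=True, slots=True)
class DayMotorResult:
    date: date | None
    bradykinesia_score: float | None
    dyskinesia_score: float | None
    n_samples: int


def daily_motor_scores(samples: Sequence[MotorSample], day: date | None = None) -> DayMotorResult:
    n = len(samples)
    if n == 0:
        return DayMotorResult(date=day, bradykinesia_score=None, dyskinesia_score=None, n_samples=0)
    return DayMotorResult(
        date=day,
        bradykinesia_score=math.fsum(s.bradykinesia for s in samples) / n,
        dyskinesia_score=math.fsum(s.dyskinesia for s in samples) / n,
        n_samples=n,
    )
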