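"""Sleep scoring from bed-sensor occupancy intervals.

A night is a chain of bed intervals (gaps under 4 h) attributed to the wake
day.  Three components in the style of the Pittsburgh Sleep Quality Index
are derived per night — sleep duration, habitual sleep efficiency and sleep
disturbances, each graded 0 (best) to 3 (worst) by rule tables — and
combined into a 0–100 daily sleep score (higher = better):

    score = 100 * (1 - (duration + efficiency + disturbances) / 9)

Rule-table boundaries left open by the strict inequalities (exactly 7, 6,
5 hours; ratio exactly 75, 65) join the less-severe bucket.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from datetime import date, datetime
from typing import Sequence

from .config import EngineConfig
from .events import BedInterval, chain_bed_intervals, night_wake_date


class DegenerateNightError(ValueError):
    """Night whose in-bed window has zero width; no efficiency is defined."""


@dataclass(frozen=True, slots=True)
class NightRecord:
    """One sleep episode: ordered bed intervals with summary quantities."""

    wake_date: date
    intervals: tuple[BedInterval, ...]
    min_time: datetime  # first time in bed
    max_time: datetime  # time the patient finally left the bed
    cumulative_hours: float  # total hours actually in bed
    interruptions: int  # out-of-bed gaps at least the minimum gap long


@dataclass(frozen=True, slots=True)
class SleepComponents:
    duration_component: int  # 0-3
    efficiency_ratio: float  # percent in [0, 100]
    efficiency_component: int  # 0-3
    disturbance_component: int  # 0-3
    sleep_score: float | None = None


def build_nights(
    intervals: Sequence[BedInterval], config: EngineConfig | None = None
) -> list[NightRecord]:
    """Chain sorted bed intervals into :class:`NightRecord` objects."""
    cfg = config or EngineConfig()
    nights = []
    for chain in chain_bed_intervals(
        intervals,
        night_chain_gap_h=cfg.night_chain_gap_h,
        night_start_after_h=cfg.night_start_after_h,
        night_start_before_h=cfg.night_start_before_h,
    ):
        nights.append(night_from_chain(chain, cfg))
    return nights


def night_from_chain(chain: Sequence[BedInterval], config: EngineConfig | None = None) -> NightRecord:
    """Summarize one interval chain as a night."""
    cfg = config or EngineConfig()
    cum = math.fsum(iv.duration_h for iv in chain)
    gaps = [
        (b.enter - a.leave).total_seconds() / 60.0 for a, b in zip(chain, chain[1:])
    ]
    interruptions = sum(1 for g in gaps if g >= cfg.min_interruption_gap_min)
    return NightRecord(
        wake_date=night_wake_date(chain),
        intervals=tuple(chain),
        min_time=chain[0].enter,
        max_time=chain[-1].leave,
        cumulative_hours=cum,
        interruptions=interruptions,
    )


def duration_component(cumulative_hours: float) -> int:
    if cumulative_hours >= 7.0:
        return 0
    if cumulative_hours >= 6.0:
        return 1
    if cumulative_hours >= 5.0:
        return 2
    return 3


def efficiency_component(ratio_percent: float) -> int:
    if ratio_percent >= 85.0:
        return 0
    if ratio_percent >= 75.0:
        return 1
    if ratio_percent >= 65.0:
        return 2
    return 3


def disturbance_component(interruptions: int) -> int:
    return min(int(interruptions), 3)


def sleep_components(night: NightRecord) -> SleepComponents:
    """Grade a night on the three 0–3 components (score left unset).

    The habitual-sleep-efficiency ratio is the percentage of the in-bed
    window (first enter to final leave) actually spent in bed.
    """
    window_h = (night.max_time - night.min_time).total_seconds() / 3600.0
    if window_h <= 0:
        raise DegenerateNightError(
            f"night of {night.wake_date}: in-bed window has zero length at {night.min_time}"
        )
    # cumulative <= window by construction; guard float round-off
    ratio = min(100.0, 100.0 * night.cumulative_hours / window_h)
    return SleepComponents(
        duration_component=duration_component(night.cumulative_hours),
        efficiency_ratio=ratio,
        efficiency_component=efficiency_component(ratio),
        disturbance_component=disturbance_component(night.interruptions),
    )


def daily_sleep_score(components: SleepComponents) -> SleepComponents:
    """Combine the three components into the 0–100 daily sleep score."""
    total = (
        components.duration_component
        + components.efficiency_component
        + components.disturbance_component
    )
    return replace(components, sleep_score=100.0 * (1.0 - total / 9.0))


def score_night(night: NightRecord) -> SleepComponents:
    """Components plus final score for one night."""
    return daily_sleep_score(sleep_components(night))
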