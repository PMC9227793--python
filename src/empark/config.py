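"""Engine configuration: every tunable of the scoring pipeline in one place.

Defaults follow the published constants of the monitoring protocol where one
exists (30-minute replacement window, 30/60-minute meal window around levodopa
intake, the >70 / 30–70 / <30 score bands, 14-day summary window); the
remaining knobs are documented design choices (see docs/methods.md).
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal

import yaml
from pydantic import BaseModel, Field


class EngineConfig(BaseModel):
    """Tunables of the daily scoring engine.

    Attributes
    ----------
    replacement_window_min:
        Half-width (minutes) of the window around a planned intake within
        which an extra dose counts as a replacement of that intake.
    deviation_max_min:
        Deviation (minutes) at which the per-occasion medication score
        reaches 0 under the linear decay mapping.
    replacement_counts_deviation:
        If True (default) a replacement dose is scored like a scheduled
        delivery, contributing its own deviation; if False the replaced
        occasion is omitted from the daily mean entirely.
    min_interruption_gap_min:
        Shortest out-of-bed gap (minutes) counted as a sleep interruption;
        shorter gaps are treated as bed-sensor jitter.
    night_chain_gap_h:
        Bed intervals separated by gaps shorter than this (hours) are chained
        into one sleep episode.
    meal_window_before_min / meal_window_after_min:
        The interval [intake - before, intake + after] around each levodopa
        intake used by the meal-timing rule.
    meal_window_mode:
        ``avoid``: a meal complies when it falls *outside* every such window
        (levodopa absorption competes with dietary protein).
        ``require``: a meal complies when it falls inside at least one window.
    summary_window_days:
        Rolling window of the patient start-page means.
    """

    replacement_window_min: float = Field(default=30.0, ge=0)
    deviation_max_min: float = Field(default=120.0, gt=0)
    replacement_counts_deviation: bool = True

    min_interruption_gap_min: float = Field(default=1.0, ge=0)
    night_chain_gap_h: float = Field(default=4.0, gt=0)
    night_start_after_h: float = Field(default=18.0, ge=0, le=24)
    night_start_before_h: float = Field(default=12.0, ge=0, le=24)

    meal_window_before_min: float = Field(default=30.0, ge=0)
    meal_window_after_min: float = Field(default=60.0, ge=0)
    meal_window_mode: Literal["avoid", "require"] = "avoid"

    summary_window_days: int = Field(default=14, ge=1)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, for run logs."""
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | None) -> EngineConfig:
    """Load an :class:`EngineConfig` from a YAML file (``None`` -> defaults)."""
    if path is None:
        return EngineConfig()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    return EngineConfig(**data)
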