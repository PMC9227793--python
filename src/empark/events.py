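"""Typed in-memory model of the raw per-patient event streams.

Six streams feed the daily scoring engine: planned and delivered medication
intakes (dosing device), bed-occupancy intervals (bed sensor), 2-minute
bradykinesia/dyskinesia samples (wrist sensor), and self-reported meals,
exercise occasions and daily quality-of-life questionnaires (tablet app).
All timestamps are timezone-naive local time at minute resolution — every
scoring formula works in minute deviations.

A :class:`Scenario` bundles one patient's streams together with the
individual exercise target.  Scenarios round-trip through a CSV bundle
(one file per stream) or a single JSON document.
"""

from __future__ import annotations

import csv
import json
import os
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Mapping, Sequence

MOTOR_SCALE = (0.0, 100.0)
EXERCISE_MODES = (1, 2, 3)
N_QOL_ITEMS = 8

#: file names of the CSV bundle, one per stream
CSV_FILES = {
    "planned_doses": "planned_doses.csv",
    "taken_doses": "taken_doses.csv",
    "bed_intervals": "bed_intervals.csv",
    "motor_samples": "motor_samples.csv",
    "meals": "meals.csv",
    "exercise": "exercise.csv",
    "qol": "qol.csv",
}


class ScenarioError(ValueError):
    """Base class for scenario input problems."""


class ParseError(ScenarioError):
    """A record could not be parsed; names the file and row."""

    def __init__(self, message: str, source: str | None = None, row: int | None = None):
        self.source = source
        self.row = row
        loc = ""
        if source is not None:
            loc = f" [{source}" + (f", row {row}" if row is not None else "") + "]"
        super().__init__(message + loc)


class ValidationError(ScenarioError):
    """A parsed record violates a stream invariant."""


# ---------------------------------------------------------------------------
# record types


@dataclass(frozen=True, slots=True)
class PlannedDose:
    time: datetime
    dose: float  # levodopa units

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"planned dose must be > 0, got {self.dose} at {self.time}")


@dataclass(frozen=True, slots=True)
class TakenDose:
    time: datetime
    dose: float
    source: str = "scheduled-delivery"  # or "extra"

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise ValidationError(f"taken dose must be > 0, got {self.dose} at {self.time}")
        if self.source not in ("scheduled-delivery", "extra"):
            raise ValidationError(f"unknown dose source {self.source!r} at {self.time}")


@dataclass(frozen=True, slots=True)
class BedInterval:
    enter: datetime
    leave: datetime

    def __post_init__(self) -> None:
        if not self.leave > self.enter:
            raise ValidationError(
                f"bed interval leave ({self.leave}) must be after enter ({self.enter})"
            )

    @property
    def duration_h(self) -> float:
        return (self.leave - self.enter).total_seconds() / 3600.0


@dataclass(frozen=True, slots=True)
class MotorSample:
    time: datetime
    bradykinesia: float  # 0-100, higher = better
    dyskinesia: float  # 0-100, higher = better

    def __post_init__(self) -> None:
        lo, hi = MOTOR_SCALE
        for name, v in (("bradykinesia", self.bradykinesia), ("dyskinesia", self.dyskinesia)):
            if not (lo <= v <= hi):
                raise ValidationError(f"{name} sample {v} outside [{lo}, {hi}] at {self.time}")


@dataclass(frozen=True, slots=True)
class MealEvent:
    time: datetime


@dataclass(frozen=True, slots=True)
class ExerciseEvent:
    time: datetime
    mode: int  # 1: boxing/dancing/running/swimming, 2: bicycling/gym, 3: walking
    duration_min: float

    def __post_init__(self) -> None:
        if self.mode not in EXERCISE_MODES:
            raise ValidationError(f"exercise mode must be in {EXERCISE_MODES}, got {self.mode}")
        if not self.duration_min > 0:
            raise ValidationError(f"exercise duration must be > 0, got {self.duration_min}")


@dataclass(frozen=True, slots=True)
class QoLResponse:
    """One day's 9-item questionnaire: 8 three-level items plus a 0-100 VAS."""

    date: date
    item_levels: tuple[int, ...]  # 8 items, levels 1 (no problems) .. 3 (extreme)
    vas: float  # overall health, 0 worst .. 100 best

    def __post_init__(self) -> None:
        if len(self.item_levels) != N_QOL_ITEMS:
            raise ValidationError(
                f"QoL response for {self.date} has {len(self.item_levels)} items, "
                f"expected {N_QOL_ITEMS}"
            )
        for i, lv in enumerate(self.item_levels, start=1):
            if lv not in (1, 2, 3):
                raise ValidationError(f"QoL item {i} level must be 1-3, got {lv} on {self.date}")
        if not (0.0 <= self.vas <= 100.0):
            raise ValidationError(f"VAS {self.vas} outside [0, 100] on {self.date}")


# ---------------------------------------------------------------------------
# scenario bundle


@dataclass
class Scenario:
    """All raw input streams of one patient, sorted by time."""

    patient_id: str = "patient"
    patient_target: float = 80.0  # individual exercise target, (0, 100]
    planned_doses: list[PlannedDose] = field(default_factory=list)
    taken_doses: list[TakenDose] = field(default_factory=list)
    bed_intervals: list[BedInterval] = field(default_factory=list)
    motor_samples: list[MotorSample] = field(default_factory=list)
    meals: list[MealEvent] = field(default_factory=list)
    exercise: list[ExerciseEvent] = field(default_factory=list)
    qol: list[QoLResponse] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sort()
        self.validate()

    def sort(self) -> None:
        self.planned_doses.sort(key=lambda r: r.time)
        self.taken_doses.sort(key=lambda r: r.time)
        self.bed_intervals.sort(key=lambda r: r.enter)
        self.motor_samples.sort(key=lambda r: r.time)
        self.meals.sort(key=lambda r: r.time)
        self.exercise.sort(key=lambda r: r.time)
        self.qol.sort(key=lambda r: r.date)

    def validate(self) -> None:
        if not (0.0 < self.patient_target <= 100.0):
            raise ValidationError(f"patient_target must be in (0, 100], got {self.patient_target}")
        for a, b in zip(self.planned_doses, self.planned_doses[1:]):
            if b.time <= a.time:
                raise ValidationError(
                    f"planned dose times must be strictly increasing: {a.time} then {b.time}"
                )
        for a, b in zip(self.bed_intervals, self.bed_intervals[1:]):
            if b.enter < a.leave:
                raise ValidationError(
                    f"bed intervals overlap: [{a.enter}, {a.leave}] and [{b.enter}, {b.leave}]"
                )
        seen: set[date] = set()
        for q in self.qol:
            if q.date in seen:
                raise ValidationError(f"duplicate QoL response for {q.date}")
            seen.add(q.date)

    def stream_counts(self) -> dict[str, int]:
        """Parse report: number of records per stream."""
        return {
            "planned_doses": len(self.planned_doses),
            "taken_doses": len(self.taken_doses),
            "bed_intervals": len(self.bed_intervals),
            "motor_samples": len(self.motor_samples),
            "meals": len(self.meals),
            "exercise": len(self.exercise),
            "qol": len(self.qol),
        }

    def date_range(self) -> list[date]:
        """Complete calendar-day axis from first to last event (inclusive)."""
        dates: list[date] = []
        for rec in self.planned_doses + self.taken_doses + self.meals + self.exercise:
            dates.append(rec.time.date())
        for s in self.motor_samples:
            dates.append(s.time.date())
        for b in self.bed_intervals:
            dates.append(b.enter.date())
            dates.append(b.leave.date())
        for q in self.qol:
            dates.append(q.date)
        if not dates:
            return []
        d0, d1 = min(dates), max(dates)
        return [d0 + timedelta(days=i) for i in range((d1 - d0).days + 1)]


# ---------------------------------------------------------------------------
# night chaining (shared with the sleep module)


def chain_bed_intervals(
    intervals: Sequence[BedInterval],
    *,
    night_chain_gap_h: float = 4.0,
    night_start_after_h: float = 18.0,
    night_start_before_h: float = 12.0,
) -> list[list[BedInterval]]:
    """Group sorted bed intervals into sleep-episode chains.

    Consecutive intervals separated by a gap shorter than ``night_chain_gap_h``
    hours belong to the same episode.  A chain qualifies as a night when it
    starts after ``night_start_after_h`` or before ``night_start_before_h``
    local time; chains starting in the afternoon (daytime naps) are dropped.
    """
    chains: list[list[BedInterval]] = []
    current: list[BedInterval] = []
    for iv in intervals:
        if current and (iv.enter - current[-1].leave) < timedelta(hours=night_chain_gap_h):
            current.append(iv)
        else:
            if current:
                chains.append(current)
            current = [iv]
    if current:
        chains.append(current)

    def is_night(chain: list[BedInterval]) -> bool:
        h = chain[0].enter.hour + chain[0].enter.minute / 60.0
        return h >= night_start_after_h or h < night_start_before_h

    return [c for c in chains if is_night(c)]


def night_wake_date(chain: Sequence[BedInterval]) -> date:
    """A night is attributed to the calendar day on which the patient last left bed."""
    return chain[-1].leave.date()


# ---------------------------------------------------------------------------
# per-day partitioning


@dataclass
class DaySlice:
    """Per-calendar-day slice of every stream.

    Point events belong to the date containing their timestamp; nights
    (chained bed intervals) are attributed to the wake day.
    """

    date: date
    planned_doses: list[PlannedDose] = field(default_factory=list)
    taken_doses: list[TakenDose] = field(default_factory=list)
    nights: list[list[BedInterval]] = field(default_factory=list)
    motor_samples: list[MotorSample] = field(default_factory=list)
    meals: list[MealEvent] = field(default_factory=list)
    exercise: list[ExerciseEvent] = field(default_factory=list)
    qol: QoLResponse | None = None


def partition_by_day(
    scenario: Scenario,
    *,
    night_chain_gap_h: float = 4.0,
    night_start_after_h: float = 18.0,
    night_start_before_h: float = 12.0,
) -> dict[date, DaySlice]:
    """Split a scenario into per-calendar-day slices over its full date range.

    Every date between the first and last event is present, so empty days
    yield empty slices (the time axis stays continuous).
    """
    out = {d: DaySlice(date=d) for d in scenario.date_range()}

    def slot(d: date) -> DaySlice:
        if d not in out:
            out[d] = DaySlice(date=d)
        return out[d]

    for r in scenario.planned_doses:
        slot(r.time.date()).planned_doses.append(r)
    for r in scenario.taken_doses:
        slot(r.time.date()).taken_doses.append(r)
    for r in scenario.motor_samples:
        slot(r.time.date()).motor_samples.append(r)
    for r in scenario.meals:
        slot(r.time.date()).meals.append(r)
    for r in scenario.exercise:
        slot(r.time.date()).exercise.append(r)
    for q in scenario.qol:
        slot(q.date).qol = q
    for chain in chain_bed_intervals(
        scenario.bed_intervals,
        night_chain_gap_h=night_chain_gap_h,
        night_start_after_h=night_start_after_h,
        night_start_before_h=night_start_before_h,
    ):
        slot(night_wake_date(chain)).nights.append(chain)
    return out


# ---------------------------------------------------------------------------
# IO


def _parse_ts(value: str, source: str, row: int) -> datetime:
    try:
        return datetime.fromisoformat(value.strip())
    except ValueError as exc:
        raise ParseError(f"malformed timestamp {value!r}: {exc}", source, row) from None


def _parse_date(value: str, source: str, row: int) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError as exc:
        raise ParseError(f"malformed date {value!r}: {exc}", source, row) from None


def _parse_num(value: str, source: str, row: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise ParseError(f"malformed {what} {value!r}", source, row) from None


def _read_rows(path: str) -> Iterable[tuple[int, dict[str, str]]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        # data rows start at 2 (header is row 1)
        for i, row in enumerate(reader, start=2):
            yield i, row


def _require(row: Mapping[str, str], key: str, source: str, rownum: int) -> str:
    v = row.get(key)
    if v is None or v == "":
        raise ParseError(f"missing field {key!r}", source, rownum)
    return v


def load_scenario(path: str, format: str | None = None) -> Scenario:
    """Load a scenario from a CSV bundle directory or a single JSON document.

    ``format`` is ``"csv-bundle"`` or ``"json-document"``; ``None``
    auto-detects (directory -> CSV bundle, file -> JSON).  Absent stream files
    in a CSV bundle yield empty streams.
    """
    if format is None:
        format = "csv-bundle" if os.path.isdir(path) else "json-document"
    if format == "csv-bundle":
        return _load_csv_bundle(path)
    if format == "json-document":
        return _load_json_document(path)
    raise ValueError(f"unrecognized scenario format {format!r}")


def _load_csv_bundle(dirpath: str) -> Scenario:
    def fpath(name: str) -> str | None:
        p = os.path.join(dirpath, CSV_FILES[name])
        return p if os.path.exists(p) else None

    def wrap(record_ctor, _src, _rownum, **kwargs):
        try:
            return record_ctor(**kwargs)
        except ValidationError as exc:
            raise ValidationError(f"{exc} [{_src}, row {_rownum}]") from None

    planned, taken, bed, motor, meals, exercise, qol = [], [], [], [], [], [], []
    if (p := fpath("planned_doses")) is not None:
        for i, row in _read_rows(p):
            planned.append(wrap(
                PlannedDose, p, i,
                time=_parse_ts(_require(row, "time", p, i), p, i),
                dose=_parse_num(_require(row, "dose", p, i), p, i, "dose"),
            ))
    if (p := fpath("taken_doses")) is not None:
        for i, row in _read_rows(p):
            taken.append(wrap(
                TakenDose, p, i,
                time=_parse_ts(_require(row, "time", p, i), p, i),
                dose=_parse_num(_require(row, "dose", p, i), p, i, "dose"),
                source=_require(row, "source", p, i).strip(),
            ))
    if (p := fpath("bed_intervals")) is not None:
        for i, row in _read_rows(p):
            bed.append(wrap(
                BedInterval, p, i,
                enter=_parse_ts(_require(row, "enter", p, i), p, i),
                leave=_parse_ts(_require(row, "leave", p, i), p, i),
            ))
    if (p := fpath("motor_samples")) is not None:
        for i, row in _read_rows(p):
            motor.append(wrap(
                MotorSample, p, i,
                time=_parse_ts(_require(row, "time", p, i), p, i),
                bradykinesia=_parse_num(_require(row, "bradykinesia", p, i), p, i, "bradykinesia"),
                dyskinesia=_parse_num(_require(row, "dyskinesia", p, i), p, i, "dyskinesia"),
            ))
    if (p := fpath("meals")) is not None:
        for i, row in _read_rows(p):
            meals.append(MealEvent(time=_parse_ts(_require(row, "time", p, i), p, i)))
    if (p := fpath("exercise")) is not None:
        for i, row in _read_rows(p):
            exercise.append(wrap(
                ExerciseEvent, p, i,
                time=_parse_ts(_require(row, "time", p, i), p, i),
                mode=int(_parse_num(_require(row, "mode", p, i), p, i, "mode")),
                duration_min=_parse_num(
                    _require(row, "duration_min", p, i), p, i, "duration"),
            ))
    if (p := fpath("qol")) is not None:
        for i, row in _read_rows(p):
            levels = tuple(
                int(_parse_num(_require(row, f"q{k}", p, i), p, i, f"q{k} level"))
                for k in range(1, N_QOL_ITEMS + 1)
            )
            qol.append(wrap(
                QoLResponse, p, i,
                date=_parse_date(_require(row, "date", p, i), p, i),
                item_levels=levels,
                vas=_parse_num(_require(row, "vas", p, i), p, i, "vas"),
            ))

    meta = {}
    mpath = os.path.join(dirpath, "scenario.json")
    if os.path.exists(mpath):
        with open(mpath, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
    return Scenario(
        patient_id=meta.get("patient_id", os.path.basename(os.path.normpath(dirpath)) or "patient"),
        patient_target=float(meta.get("patient_target", 80.0)),
        planned_doses=planned, taken_doses=taken, bed_intervals=bed,
        motor_samples=motor, meals=meals, exercise=exercise, qol=qol,
    )


def _load_json_document(path: str) -> Scenario:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"invalid JSON: {exc}", path) from None

    def ts(v, i, stream):
        return _parse_ts(str(v), f"{path}#{stream}", i)

    return Scenario(
        patient_id=str(doc.get("patient_id", "patient")),
        patient_target=float(doc.get("patient_target", 80.0)),
        planned_doses=[
            PlannedDose(time=ts(r["time"], i, "planned_doses"), dose=float(r["dose"]))
            for i, r in enumerate(doc.get("planned_doses", []))
        ],
        taken_doses=[
            TakenDose(time=ts(r["time"], i, "taken_doses"), dose=float(r["dose"]),
                      source=r.get("source", "scheduled-delivery"))
            for i, r in enumerate(doc.get("taken_doses", []))
        ],
        bed_intervals=[
            BedInterval(enter=ts(r["enter"], i, "bed_intervals"),
                        leave=ts(r["leave"], i, "bed_intervals"))
            for i, r in enumerate(doc.get("bed_intervals", []))
        ],
        motor_samples=[
            MotorSample(time=ts(r["time"], i, "motor_samples"),
                        bradykinesia=float(r["bradykinesia"]),
                        dyskinesia=float(r["dyskinesia"]))
            for i, r in enumerate(doc.get("motor_samples", []))
        ],
        meals=[MealEvent(time=ts(r["time"], i, "meals")) for i, r in enumerate(doc.get("meals", []))],
        exercise=[
            ExerciseEvent(time=ts(r["time"], i, "exercise"), mode=int(r["mode"]),
                          duration_min=float(r["duration_min"]))
            for i, r in enumerate(doc.get("exercise", []))
        ],
        qol=[
            QoLResponse(date=_parse_date(str(r["date"]), f"{path}#qol", i),
                        item_levels=tuple(int(x) for x in r["item_levels"]),
                        vas=float(r["vas"]))
            for i, r in enumerate(doc.get("qol", []))
        ],
    )


def _iso(dt: datetime) -> str:
    return dt.isoformat(sep="T", timespec="minutes") if dt.second == 0 and dt.microsecond == 0 \
        else dt.isoformat(sep="T")


def write_scenario(scenario: Scenario, path: str, format: str = "csv-bundle") -> None:
    """Write a scenario as a CSV bundle (directory) or single JSON document."""
    if format == "csv-bundle":
        _write_csv_bundle(scenario, path)
    elif format == "json-document":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(scenario_to_dict(scenario), fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unrecognized scenario format {format!r}")


def _write_csv_bundle(scenario: Scenario, dirpath: str) -> None:
    os.makedirs(dirpath, exist_ok=True)

    def dump(name: str, header: list[str], rows: list[list]) -> None:
        with open(os.path.join(dirpath, CSV_FILES[name]), "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(header)
            w.writerows(rows)

    dump("planned_doses", ["time", "dose"],
         [[_iso(r.time), r.dose] for r in scenario.planned_doses])
    dump("taken_doses", ["time", "dose", "source"],
         [[_iso(r.time), r.dose, r.source] for r in scenario.taken_doses])
    dump("bed_intervals", ["enter", "leave"],
         [[_iso(r.enter), _iso(r.leave)] for r in scenario.bed_intervals])
    dump("motor_samples", ["time", "bradykinesia", "dyskinesia"],
         [[_iso(r.time), r.bradykinesia, r.dyskinesia] for r in scenario.motor_samples])
    dump("meals", ["time"], [[_iso(r.time)] for r in scenario.meals])
    dump("exercise", ["time", "mode", "duration_min"],
         [[_iso(r.time), r.mode, r.duration_min] for r in scenario.exercise])
    dump("qol", ["date"] + [f"q{k}" for k in range(1, N_QOL_ITEMS + 1)] + ["vas"],
         [[r.date.isoformat(), *r.item_levels, r.vas] for r in scenario.qol])
    with open(os.path.join(dirpath, "scenario.json"), "w", encoding="utf-8") as fh:
        json.dump({"patient_id": scenario.patient_id,
                   "patient_target": scenario.patient_target}, fh, indent=1)
        fh.write("\n")


def scenario_to_dict(scenario: Scenario) -> dict:
    """JSON-document representation of a scenario (one array per stream)."""
    return {
        "patient_id": scenario.patient_id,
        "patient_target": scenario.patient_target,
        "planned_doses": [{"time": _iso(r.time), "dose": r.dose} for r in scenario.planned_doses],
        "taken_doses": [
            {"time": _iso(r.time), "dose": r.dose, "source": r.source}
            for r in scenario.taken_doses
        ],
        "bed_intervals": [
            {"enter": _iso(r.enter), "leave": _iso(r.leave)} for r in scenario.bed_intervals
        ],
        "motor_samples": [
            {"time": _iso(r.time), "bradykinesia": r.bradykinesia, "dyskinesia": r.dyskinesia}
            for r in scenario.motor_samples
        ],
        "meals": [{"time": _iso(r.time)} for r in scenario.meals],
        "exercise": [
            {"time": _iso(r.time), "mode": r.mode, "duration_min": r.duration_min}
            for r in scenario.exercise
        ],
        "qol": [
            {"date": r.date.isoformat(), "item_levels": list(r.item_levels), "vas": r.vas}
            for r in scenario.qol
        ],
    }
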