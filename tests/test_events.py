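"""Event-stream model: parsing, validation, round trips and day partitioning."""

from datetime import date, datetime, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from empark.events import (
    BedInterval,
    MealEvent,
    MotorSample,
    PlannedDose,
    ParseError,
    QoLResponse,
    Scenario,
    TakenDose,
    ValidationError,
    chain_bed_intervals,
    load_scenario,
    night_wake_date,
    partition_by_day,
    write_scenario,
)
from empark.simulate import SimConfig, simulate_scenario

from conftest import DAY, ts


class TestRecordInvariants:
    def test_bed_interval_leave_before_enter_rejected(self):
        with pytest.raises(ValidationError):
            BedInterval(enter=ts(7), leave=ts(6))

    @pytest.mark.parametrize("brady,dysk", [(-1, 50), (50, 101), (150, 150)])
    def test_motor_sample_outside_scale_rejected(self, brady, dysk):
        with pytest.raises(ValidationError):
            MotorSample(time=ts(10), bradykinesia=brady, dyskinesia=dysk)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValidationError):
            PlannedDose(time=ts(8), dose=0.0)
        with pytest.raises(ValidationError):
            TakenDose(time=ts(8), dose=-5.0)

    def test_qol_level_and_count_validation(self):
        with pytest.raises(ValidationError):
            QoLResponse(date=DAY, item_levels=(1,) * 7, vas=50)
        with pytest.raises(ValidationError):
            QoLResponse(date=DAY, item_levels=(1, 1, 1, 0, 1, 1, 1, 1), vas=50)
        with pytest.raises(ValidationError):
            QoLResponse(date=DAY, item_levels=(1,) * 8, vas=120)

    def test_planned_times_must_strictly_increase(self):
        with pytest.raises(ValidationError):
            Scenario(planned_doses=[PlannedDose(ts(8), 100), PlannedDose(ts(8), 100)])

    def test_overlapping_bed_intervals_rejected(self):
        with pytest.raises(ValidationError):
            Scenario(bed_intervals=[BedInterval(ts(22), ts(23, 30)),
                                    BedInterval(ts(23), ts(23, 45))])


class TestScenarioIO:
    def test_empty_scenario_loads_with_six_empty_streams(self, tmp_path):
        write_scenario(Scenario(), tmp_path / "b", format="csv-bundle")
        sc = load_scenario(str(tmp_path / "b"))
        assert all(v == 0 for v in sc.stream_counts().values())

    def test_counts_match_independent_line_count(self, tmp_path):
        sc = Scenario(
            planned_doses=[PlannedDose(ts(8), 100), PlannedDose(ts(12), 100),
                           PlannedDose(ts(16), 100)],
            taken_doses=[TakenDose(ts(8, 4), 100), TakenDose(ts(12, 1), 100),
                         TakenDose(ts(16, 30), 100)],
            bed_intervals=[BedInterval(ts(23), ts(7, 0, day=1))],
        )
        write_scenario(sc, tmp_path / "b", format="csv-bundle")
        # independent oracle: data rows = physical lines minus header
        def data_lines(name):
            text = (tmp_path / "b" / name).read_text().strip().splitlines()
            return len(text) - 1
        loaded = load_scenario(str(tmp_path / "b"))
        counts = loaded.stream_counts()
        assert counts["planned_doses"] == data_lines("planned_doses.csv") == 3
        assert counts["taken_doses"] == data_lines("taken_doses.csv") == 3
        assert counts["bed_intervals"] == data_lines("bed_intervals.csv") == 1
        assert (counts["motor_samples"], counts["meals"], counts["exercise"],
                counts["qol"]) == (0, 0, 0, 0)

    @pytest.mark.parametrize("fmt", ["csv-bundle", "json-document"])
    def test_round_trip_preserves_every_record(self, tmp_path, fmt):
        sc, _ = simulate_scenario(SimConfig(seed=3, days=3))
        path = tmp_path / ("b" if fmt == "csv-bundle" else "scenario.json")
        write_scenario(sc, str(path), format=fmt)
        back = load_scenario(str(path), format=fmt)
        assert back.planned_doses == sc.planned_doses
        assert back.taken_doses == sc.taken_doses
        assert back.bed_intervals == sc.bed_intervals
        assert back.motor_samples == sc.motor_samples
        assert back.meals == sc.meals
        assert back.exercise == sc.exercise
        assert back.qol == sc.qol
        assert back.patient_target == sc.patient_target

    def test_malformed_timestamp_names_file_and_row(self, tmp_path):
        d = tmp_path / "b"
        d.mkdir()
        (d / "meals.csv").write_text("time\n2021-03-01T08:00\nnot-a-time\n")
        with pytest.raises(ParseError) as exc:
            load_scenario(str(d))
        assert "meals.csv" in str(exc.value) and "row 3" in str(exc.value)

    def test_invalid_record_names_stream(self, tmp_path):
        d = tmp_path / "b"
        d.mkdir()
        (d / "bed_intervals.csv").write_text(
            "enter,leave\n2021-03-01T23:00,2021-03-01T22:00\n")
        with pytest.raises(ValidationError) as exc:
            load_scenario(str(d))
        assert "bed_intervals.csv" in str(exc.value)

    def test_missing_stream_file_yields_empty_stream(self, tmp_path):
        d = tmp_path / "b"
        d.mkdir()
        (d / "meals.csv").write_text("time\n2021-03-01T08:00\n")
        sc = load_scenario(str(d))
        assert sc.stream_counts()["meals"] == 1
        assert sc.stream_counts()["bed_intervals"] == 0


class TestPartition:
    def test_point_events_assigned_to_containing_date(self):
        sc = Scenario(taken_doses=[TakenDose(ts(h), 100) for h in (6, 9, 12, 15, 18)])
        parts = partition_by_day(sc)
        assert list(parts) == [DAY]
        assert len(parts[DAY].taken_doses) == 5

    def test_midnight_boundary_splits_meals(self):
        sc = Scenario(meals=[MealEvent(ts(23, 59)), MealEvent(ts(0, 1, day=1))])
        parts = partition_by_day(sc)
        assert len(parts[DAY].meals) == 1
        assert len(parts[date(2021, 3, 2)].meals) == 1

    def test_night_crossing_midnight_goes_to_wake_day(self):
        sc = Scenario(bed_intervals=[BedInterval(ts(22, 30), ts(6, 30, day=1))])
        parts = partition_by_day(sc)
        wake = date(2021, 3, 2)
        assert parts[wake].nights and parts[wake].nights[0][0].enter == ts(22, 30)
        assert not parts[DAY].nights

    def test_afternoon_nap_excluded_from_nights(self):
        chains = chain_bed_intervals([BedInterval(ts(14), ts(15, 30))])
        assert chains == []

    def test_chain_gap_rule_splits_episodes(self):
        early = BedInterval(ts(22), ts(23))
        late = BedInterval(ts(4, 0, day=1), ts(7, 0, day=1))  # 5 h gap -> new episode
        chains = chain_bed_intervals([early, late])
        assert len(chains) == 2
        assert night_wake_date(chains[0]) == DAY
        assert night_wake_date(chains[1]) == date(2021, 3, 2)

    def test_empty_days_keep_axis_continuous(self):
        sc = Scenario(meals=[MealEvent(ts(12)), MealEvent(ts(12, 0, day=3))])
        parts = partition_by_day(sc)
        assert sorted(parts) == [DAY + timedelta(days=i) for i in range(4)]
        assert not parts[DAY + timedelta(days=1)].meals

    @settings(max_examples=25, deadline=None)
    @given(st.data())
    def test_partition_conserves_events(self, data):
        n = data.draw(st.integers(0, 30))
        times = sorted(
            data.draw(st.lists(
                st.datetimes(min_value=datetime(2021, 3, 1),
                             max_value=datetime(2021, 3, 10)),
                min_size=n, max_size=n))
        )
        sc = Scenario(meals=[MealEvent(t) for t in times])
        parts = partition_by_day(sc)
        assert sum(len(s.meals) for s in parts.values()) == n

    def test_partition_conserves_simulated_streams(self):
        sc, _ = simulate_scenario(SimConfig(seed=7, days=5))
        parts = partition_by_day(sc)
        counts = sc.stream_counts()
        assert sum(len(s.planned_doses) for s in parts.values()) == counts["planned_doses"]
        assert sum(len(s.taken_doses) for s in parts.values()) == counts["taken_doses"]
        assert sum(len(s.motor_samples) for s in parts.values()) == counts["motor_samples"]
        assert sum(len(s.meals) for s in parts.values()) == counts["meals"]
        assert sum(len(s.exercise) for s in parts.values()) == counts["exercise"]
        assert sum(len(c) for s in parts.values() for c in s.nights) == counts["bed_intervals"]
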