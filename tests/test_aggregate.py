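"""Daily summary assembly, rolling means, bands and correlation."""

from datetime import timedelta

import numpy as np
import pandas as pd
import pytest

from empark.aggregate import (
    ALL_COLUMNS,
    InsufficientDataError,
    SCORE_COLUMNS,
    assemble_daily_summary,
    band_report,
    classify_score,
    correlate_scores,
    read_scores_csv,
    rolling_summary,
    score_scenario,
    write_scores_csv,
)
from empark.lifestyle import DayMealResult
from empark.simulate import SimConfig, simulate_scenario

from conftest import DAY


def frame(**cols):
    n = max(len(v) for v in cols.values())
    data = {"date": pd.date_range("2021-03-01", periods=n)}
    for k, v in cols.items():
        data[k] = list(v) + [np.nan] * (n - len(v))
    for c in ALL_COLUMNS:
        data.setdefault(c, [np.nan] * n)
    return pd.DataFrame(data)


class TestAssemble:
    def test_missing_streams_stay_missing(self):
        row = assemble_daily_summary(DAY)
        assert all(getattr(row, c) is None for c in SCORE_COLUMNS)

    def test_date_mismatch_rejected(self):
        meal = DayMealResult(date=DAY + timedelta(days=1), nwi=1, n=1, meal_score=100.0)
        with pytest.raises(ValueError):
            assemble_daily_summary(DAY, meal=meal)

    def test_scenario_frame_has_complete_date_axis(self):
        scenario, _ = simulate_scenario(SimConfig(seed=5, days=6))
        df = score_scenario(scenario)
        dates = df["date"].dt.date.tolist()
        assert dates == [min(dates) + timedelta(days=i) for i in range(len(dates))]
        # leading row (night of day 0 starts the evening before) is all-missing
        assert df.iloc[0][list(SCORE_COLUMNS)].isna().all()

    def test_motor_average_column_is_optional_mean(self):
        scenario, _ = simulate_scenario(SimConfig(seed=5, days=3))
        df = score_scenario(scenario, include_motor_average=True)
        row = df.dropna(subset=["bradykinesia"]).iloc[0]
        assert row["motor"] == pytest.approx(
            (row["bradykinesia"] + row["dyskinesia"]) / 2)


class TestBands:
    @pytest.mark.parametrize("value,band,color", [
        (71.0, "good", "green"),
        (70.0, "average", "gray"),
        (30.0, "average", "gray"),
        (29.9, "bad", "orange"),
        (0.0, "bad", "orange"),
        (100.0, "good", "green"),
    ])
    def test_thresholds(self, value, band, color):
        b = classify_score(value)
        assert (b.band, b.color) == (band, color)

    def test_missing_value_has_no_band(self):
        assert classify_score(None) is None
        assert classify_score(float("nan")) is None

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_score(101.0)

    def test_band_agrees_with_brute_force_recheck(self):
        for v in np.linspace(0, 100, 501):
            b = classify_score(float(v))
            expected = "good" if v > 70 else ("bad" if v < 30 else "average")
            assert b.band == expected


class TestRolling:
    def test_constant_window(self):
        df = frame(medication=[100.0] * 14)
        assert rolling_summary(df, 14)["medication"] == pytest.approx(100.0)

    def test_missing_values_excluded_pairwise(self):
        vals = [80.0, np.nan] * 7
        df = frame(medication=vals)
        assert rolling_summary(df, 14)["medication"] == pytest.approx(80.0)

    def test_arithmetic_mean(self):
        df = frame(sleep=list(map(float, range(14))))
        assert rolling_summary(df, 14)["sleep"] == pytest.approx(6.5)

    def test_window_one_equals_last_row(self):
        df = frame(medication=[10.0, 20.0, 30.0], meal=[1.0, 2.0, 3.0])
        means = rolling_summary(df, 1)
        assert means["medication"] == 30.0 and means["meal"] == 3.0

    def test_all_missing_stays_missing_in_band_report(self):
        df = frame(medication=[np.nan] * 5)
        rep = band_report(rolling_summary(df, 5).to_dict())
        assert rep["medication"]["band"] is None


class TestCorrelation:
    def test_self_correlation_is_one(self):
        df = frame(medication=[10.0, 50.0, 90.0, 30.0])
        rep = correlate_scores(df, "medication", "medication")
        assert rep.coefficient == pytest.approx(1.0)
        assert rep.n == 4

    def test_anti_correlation(self):
        x = [10.0, 50.0, 90.0, 30.0]
        df = frame(medication=x, sleep=[100.0 - v for v in x])
        rep = correlate_scores(df, "medication", "sleep")
        assert rep.coefficient == pytest.approx(-1.0)

    def test_symmetric_at_lag_zero(self):
        rng = np.random.default_rng(0)
        df = frame(medication=rng.uniform(0, 100, 20), sleep=rng.uniform(0, 100, 20))
        a = correlate_scores(df, "medication", "sleep")
        b = correlate_scores(df, "sleep", "medication")
        assert a.coefficient == pytest.approx(b.coefficient)

    def test_lag_alignment_recovers_shifted_copy(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 15)
        y = np.roll(x, 2)  # y[d] = x[d-2], i.e. y lags x by 2 days
        df = frame(medication=x[:-2], sleep=y[:-2])
        rep = correlate_scores(df, "medication", "sleep", lag_days=2)
        assert rep.coefficient == pytest.approx(1.0)
        assert rep.n == 11

    def test_insufficient_pairs(self):
        df = frame(medication=[10.0, 20.0], sleep=[30.0, np.nan])
        with pytest.raises(InsufficientDataError):
            correlate_scores(df, "medication", "sleep")

    def test_unknown_score_name(self):
        df = frame(medication=[1.0, 2.0, 3.0])
        with pytest.raises(KeyError):
            correlate_scores(df, "medication", "banana")

    def test_spearman_flag(self):
        x = [1.0, 2.0, 3.0, 4.0, 50.0]
        df = frame(medication=x, sleep=[v**3 / 1300 for v in x])
        rep = correlate_scores(df, "medication", "sleep", method="spearman")
        assert rep.coefficient == pytest.approx(1.0)

    def test_coupled_simulation_gives_positive_coefficient(self):
        """Dose-locked motor response: days with missed doses lose both
        medication score and motor-bump exposure, so the correlation between
        the two daily scores is positive in nearly all seeded runs."""
        cfg = dict(days=21, miss_prob=0.3, dose_response_amplitude=40.0,
                   motor_noise_sd=3.0, adherence_sd_min=10.0)
        positives = 0
        runs = 40
        for seed in range(runs):
            scenario, _ = simulate_scenario(SimConfig(seed=seed, **cfg))
            df = score_scenario(scenario)
            rep = correlate_scores(df, "medication", "bradykinesia")
            positives += rep.coefficient > 0
        assert positives >= 0.95 * runs


class TestScoresCsv:
    def test_round_trip(self, tmp_path):
        scenario, _ = simulate_scenario(SimConfig(seed=2, days=4))
        df = score_scenario(scenario)
        p = tmp_path / "scores.csv"
        write_scores_csv(df, p)
        back = read_scores_csv(p)
        assert list(back.columns) == list(df.columns)
        for c in SCORE_COLUMNS:
            a, b = df[c].to_numpy(), back[c].to_numpy()
            assert np.allclose(a, b, equal_nan=True, atol=1e-4)

    def test_missing_cells_are_empty(self, tmp_path):
        scenario, _ = simulate_scenario(SimConfig(seed=2, days=2))
        df = score_scenario(scenario)
        p = tmp_path / "scores.csv"
        write_scores_csv(df, p)
        first_row = p.read_text().splitlines()[1]
        assert ",," in first_row  # leading all-missing day serializes as empty cells
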