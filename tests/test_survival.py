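"""Retrograde survival: observations, product-limit curve, hazard, t_f rules."""

import numpy as np
import pandas as pd
import pytest

from lookback import (
    DIABETES,
    CEIThresholds,
    LPGrid,
    build_observations,
    first_hazard_below,
    hazard_curve,
    km_curve,
    recommend_lp,
    s_frequency,
    stable_s_day,
)

from conftest import make_claims


def obs_frame(times, events):
    return pd.DataFrame(
        {
            "patient_id": [f"P{i}" for i in range(len(times))],
            "time": times,
            "event": events,
        }
    )


def product_limit_oracle(times, events, day):
    """Hand-rolled Kaplan-Meier at one day, independent of the implementation."""
    s = 1.0
    for t in sorted(set(t for t, e in zip(times, events) if e)):
        if t > day:
            break
        n_t = sum(1 for u in times if u >= t)
        d_t = sum(1 for u, e in zip(times, events) if e and u == t)
        s *= 1 - d_t / n_t
    return s


class TestBuildObservations:
    def test_event_time_is_calendar_day_difference(self):
        rows = [
            ("A", "f", "1960-01-01", "inpatient", "2020-06-01", "E11.9"),
            ("A", "f", "1960-01-01", "outpatient", "2019-12-01", "E11.9"),
        ]
        obs = build_observations(
            make_claims(rows), DIABETES, 2020, pd.Timestamp("2016-01-01")
        )
        row = obs.iloc[0]
        assert row["event"] and row["time"] == 183
        assert row["a"] == pd.Timestamp("2020-06-01")
        assert row["b"] == pd.Timestamp("2019-12-01")

    def test_censored_time_runs_to_window_start(self):
        rows = [("A", "f", "1960-01-01", "inpatient", "2020-06-01", "E11.9")]
        obs = build_observations(
            make_claims(rows), DIABETES, 2020, pd.Timestamp("2016-01-01")
        )
        row = obs.iloc[0]
        assert not row["event"] and row["time"] == 1613

    def test_other_disease_lp_records_do_not_count_as_events(self):
        rows = [
            ("A", "f", "1960-01-01", "inpatient", "2020-06-01", "E11.9"),
            ("A", "f", "1960-01-01", "outpatient", "2019-06-01", "I10"),
        ]
        obs = build_observations(
            make_claims(rows), DIABETES, 2020, pd.Timestamp("2016-01-01")
        )
        assert not obs.iloc[0]["event"]

    def test_a_is_last_index_year_record_and_b_most_recent_lp_record(self):
        rows = [
            ("A", "f", "1960-01-01", "inpatient", "2020-02-01", "E11.9"),
            ("A", "f", "1960-01-01", "inpatient", "2020-09-01", "E11.9"),
            ("A", "f", "1960-01-01", "outpatient", "2018-01-01", "E11.9"),
            ("A", "f", "1960-01-01", "outpatient", "2019-10-01", "E11.9"),
        ]
        obs = build_observations(
            make_claims(rows), DIABETES, 2020, pd.Timestamp("2016-01-01")
        )
        row = obs.iloc[0]
        assert row["a"] == pd.Timestamp("2020-09-01")
        assert row["b"] == pd.Timestamp("2019-10-01")

    def test_pooled_patient_without_index_record_excluded_with_warning(self, caplog):
        rows = [("A", "f", "1960-01-01", "inpatient", "2020-06-01", "E11.9")]
        with caplog.at_level("WARNING", logger="lookback.survival"):
            obs = build_observations(
                make_claims(rows), DIABETES, 2020, pd.Timestamp("2016-01-01"),
                pool={"A", "GHOST"},
            )
        assert len(obs) == 1
        assert "no index-year disease record" in caplog.text


class TestKMCurve:
    def test_hand_computed_three_observation_example(self):
        # events at days 2 and 4, censored at 3
        curve = km_curve(obs_frame([2, 3, 4], [True, False, True]))
        assert curve.loc[0, "S"] == 1.0
        assert curve.loc[2, "S"] == pytest.approx(2 / 3)
        assert curve.loc[3, "S"] == pytest.approx(2 / 3)  # censoring leaves S flat
        assert curve.loc[4, "S"] == pytest.approx(0.0)
        assert curve["n_t"].tolist() == [3, 3, 3, 2, 1]
        assert curve["d_t"].tolist() == [0, 0, 1, 0, 1]

    def test_all_censored_curve_stays_at_one(self):
        curve = km_curve(obs_frame([5, 9, 9], [False] * 3))
        assert (curve["S"] == 1.0).all()
        assert curve.index.max() == 9

    def test_no_censoring_equals_one_minus_ecdf(self):
        rng = np.random.default_rng(11)
        times = rng.integers(1, 300, size=1000)
        curve = km_curve(obs_frame(times, [True] * 1000))
        days = curve.index.to_numpy()
        ecdf = np.searchsorted(np.sort(times), days, side="right") / len(times)
        np.testing.assert_allclose(curve["S"].to_numpy(), 1 - ecdf, atol=1e-12)

    def test_matches_product_limit_oracle_with_censoring(self):
        rng = np.random.default_rng(5)
        times = rng.integers(1, 60, size=200)
        events = rng.random(200) < 0.7
        curve = km_curve(obs_frame(times, events))
        for day in (1, 7, 20, 45, 59):
            assert curve.loc[day, "S"] == pytest.approx(
                product_limit_oracle(times, events, day)
            )

    def test_invariant_to_observation_order(self):
        rng = np.random.default_rng(7)
        times = rng.integers(1, 50, size=120)
        events = rng.random(120) < 0.6
        base = km_curve(obs_frame(times, events))
        perm = rng.permutation(120)
        shuffled = km_curve(obs_frame(times[perm], events[perm]))
        pd.testing.assert_frame_equal(base, shuffled)

    def test_event_total_and_monotonicity(self):
        rng = np.random.default_rng(13)
        times = rng.integers(1, 80, size=150)
        events = rng.random(150) < 0.5
        curve = km_curve(obs_frame(times, events))
        assert int(curve["d_t"].sum()) == int(events.sum())
        assert (np.diff(curve["S"]) <= 1e-12).all()
        assert (np.diff(curve["n_t"]) <= 0).all()


class TestHazard:
    def test_daily_hazard_is_events_over_risk_set(self):
        curve = km_curve(obs_frame([2, 3, 4], [True, False, True]))
        haz = hazard_curve(curve)
        assert haz.loc[2, "h"] == pytest.approx(1 / 3)
        assert haz.loc[1, "h"] == 0.0

    def test_windowed_hazard_equals_brute_force_sums(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 120, size=400)
        events = rng.random(400) < 0.8
        curve = km_curve(obs_frame(times, events))
        w = 7
        haz = hazard_curve(curve, window=w)
        d = curve["d_t"].to_numpy()
        n = curve["n_t"].to_numpy()
        for day in (1, 10, 50, int(haz.index.max())):
            assert haz.loc[day, "h"] == pytest.approx(d[day : day + w].sum() / n[day])

    def test_hazard_bounded_and_truncated_at_empty_risk_set(self):
        curve = km_curve(obs_frame([2, 2, 3], [True, True, True]))
        haz = hazard_curve(curve)
        assert ((haz["h"] >= 0) & (haz["h"] <= 1)).all()
        assert haz.index.max() == 3  # nothing at risk afterwards


class TestFirstHazardBelow:
    def test_never_crossing_returns_none(self):
        haz = pd.DataFrame({"h": [0.001] * 50}, index=pd.RangeIndex(1, 51, name="day"))
        assert first_hazard_below(haz, 0.0005) is None

    def test_crossing_day_found_by_scan(self):
        h = np.where(np.arange(1, 201) < 100, 0.01, 0.0004)
        haz = pd.DataFrame({"h": h}, index=pd.RangeIndex(1, 201, name="day"))
        assert first_hazard_below(haz, 0.0005) == 100

    def test_min_day_skips_spurious_early_zeroes(self):
        h = np.full(300, 0.01)
        h[4] = 0.0  # an empty early day
        h[249:] = 0.0002
        haz = pd.DataFrame({"h": h}, index=pd.RangeIndex(1, 301, name="day"))
        assert first_hazard_below(haz, 0.0005) == 5
        assert first_hazard_below(haz, 0.0005, min_day=10) == 250


class TestSFrequency:
    def test_constant_curve(self):
        curve = pd.DataFrame(
            {"S": [1.0] * 11, "n_t": 10, "d_t": 0}, index=pd.RangeIndex(0, 11, name="day")
        )
        freq = s_frequency(curve)
        assert freq.set_index("s_value")["n_days"].to_dict() == {1.0: 10}

    def test_two_level_curve_binning(self):
        s = [1.0] * 4 + [0.5] * 7  # day 0 excluded from counting
        curve = pd.DataFrame(
            {"S": s, "n_t": 10, "d_t": 0}, index=pd.RangeIndex(0, 11, name="day")
        )
        freq = s_frequency(curve)
        assert freq.set_index("s_value")["n_days"].to_dict() == {1.0: 3, 0.5: 7}

    def test_total_days_conserved_on_random_curve(self):
        rng = np.random.default_rng(21)
        times = rng.integers(1, 90, size=300)
        curve = km_curve(obs_frame(times, [True] * 300))
        freq = s_frequency(curve)
        assert freq["n_days"].sum() == curve.index.max()


def step_curve(segments):
    """Curve from (s_value, n_days) segments, day 1 onward."""
    s = [1.0] + [v for v, n in segments for _ in range(n)]
    return pd.DataFrame(
        {"S": s, "n_t": 1, "d_t": 0}, index=pd.RangeIndex(0, len(s), name="day")
    )


class TestStableS:
    def test_jump_and_peak_selects_published_style_plateau(self):
        # dwell times 50 -> 169 -> 408: the doubling into the overall peak
        # marks 0.10 as the stable value, first reached on day 220
        curve = step_curve([(0.12, 50), (0.11, 169), (0.10, 408)])
        freq = s_frequency(curve)
        assert stable_s_day(freq, curve) == (0.10, 220)

    def test_strictly_decreasing_frequencies_give_none(self):
        curve = step_curve([(0.5, 40), (0.4, 20), (0.3, 10)])
        freq = s_frequency(curve)
        assert stable_s_day(freq, curve) is None

    def test_engineered_plateau_found_at_first_day(self):
        curve = step_curve([(0.9, 10), (0.8, 12), (0.7, 9), (0.6, 100)])
        freq = s_frequency(curve)
        stable, day = stable_s_day(freq, curve)
        assert stable == 0.6
        assert day == 10 + 12 + 9 + 1

    def test_jump_without_peak_is_not_stable(self):
        # 0.8 doubles 0.9's dwell but the overall peak is at 0.6
        curve = step_curve([(0.9, 10), (0.8, 30), (0.7, 9), (0.6, 100)])
        freq = s_frequency(curve)
        stable, _ = stable_s_day(freq, curve)
        assert stable == 0.6


def published_cei_rows():
    return pd.DataFrame(
        {
            "lp_years": [0.25, 0.5, 0.75, 1.0, 2.0, 3.0, 4.0],
            "n_incident": [29407, 26195, 24172, 23288, 21472, 20468, 19806],
            "ppv": [0.674, 0.756, 0.819, 0.850, 0.922, 0.968, 1.0],
            "kappa": [0.751, 0.825, 0.876, 0.899, 0.950, 0.980, np.nan],
            "overestimation": [0.485, 0.323, 0.220, 0.176, 0.084, 0.033, 0.0],
        }
    )


class TestRecommendLP:
    def test_published_configuration_recommends_two_years(self):
        grid = LPGrid(index_year=2020)
        res = recommend_lp(published_cei_rows(), 417, 480, grid, CEIThresholds())
        assert res.recommended_lp_years == 2.0

    def test_all_pass_at_smallest_lp(self):
        rows = pd.DataFrame(
            {
                "lp_years": [1.0, 2.0],
                "n_incident": [100, 100],
                "ppv": [1.0, 1.0],
                "kappa": [0.99, np.nan],
                "overestimation": [0.0, 0.0],
            }
        )
        grid = LPGrid(index_year=2020, lp_years=(1.0, 2.0))
        res = recommend_lp(rows, 100, 50, grid)
        assert res.recommended_lp_years == 1.0

    def test_late_convergence_overrides_passing_ceis(self):
        rows = published_cei_rows()
        grid = LPGrid(index_year=2020)
        res = recommend_lp(rows, 800, None, grid)
        # 2 years = 730.5 days < 800: pushed to 3 years despite passing CEIs
        assert res.recommended_lp_years == 3.0

    def test_no_qualifying_lp_reports_diagnostics(self):
        rows = published_cei_rows()
        grid = LPGrid(index_year=2020)
        res = recommend_lp(rows, 365.25 * 5, None, grid)
        assert res.recommended_lp_years is None
        assert "covers t_f: no" in res.diagnostics

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            LPGrid(index_year=2020, lp_years=())
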