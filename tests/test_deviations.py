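"""Chi-square deviations, ranking, recurrence intervals and event merging."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import sentiwatch as sw
from sentiwatch.deviations import (
    add_recurrence_intervals,
    chi2_deviation,
    merge_events,
    rank_deviations,
    recurrence_interval,
)


def _dev_frame(rows):
    defaults = {
        "city": "A", "country": "X", "local_date": "2017-10-01", "local_hour": 10,
        "outcome": "negative", "n": 100, "observed": 50.0, "expected": 40.0,
        "direction": "excess",
    }
    out = pd.DataFrame([{**defaults, **r} for r in rows])
    if "chi2" not in out.columns:
        out["chi2"] = [
            chi2_deviation(r.observed, r.expected, r.n)[0] for r in out.itertuples()
        ]
    out["p_value"] = stats.chi2.sf(out["chi2"], df=1)
    out["direction"] = np.where(out["observed"] > out["expected"], "excess", "deficit")
    return out


class TestChiSquare:
    def test_null_gives_zero_statistic_unit_p(self):
        chi2, p, _ = chi2_deviation(40, 40, 100)
        assert chi2 == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # O=60, E=40, n=100: 400/40 + 400/60 = 16.666...
        chi2, p, direction = chi2_deviation(60, 40, 100)
        assert chi2 == pytest.approx(50 / 3, rel=1e-12)
        assert direction == "excess"
        assert p == pytest.approx(float(stats.chi2.sf(50 / 3, 1)))

    def test_direction_follows_sign(self):
        assert chi2_deviation(30, 40, 100)[2] == "deficit"

    def test_monotone_in_expected_spread(self):
        # fixed |O - E|: statistic shrinks as E(n - E) grows
        n = 1000
        stats_on_grid = [
            chi2_deviation(E + 50, E, n)[0] for E in [100, 200, 300, 400, 500]
        ]
        assert all(a > b for a, b in zip(stats_on_grid, stats_on_grid[1:]))

    def test_invalid_expected_rejected(self):
        with pytest.raises(ValueError):
            chi2_deviation(10, 0, 100)
        with pytest.raises(ValueError):
            chi2_deviation(10, 100, 100)

    def test_matches_generic_goodness_of_fit(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n = int(rng.integers(10, 1000))
            E = float(rng.uniform(0.5, n - 0.5))
            O = int(rng.integers(0, n + 1))
            chi2, p, _ = chi2_deviation(O, E, n)
            ref = stats.chisquare([O, n - O], f_exp=[E, n - E])
            assert chi2 == pytest.approx(float(ref.statistic), rel=1e-12, abs=1e-12)
            assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


class TestExpectedCounts:
    def test_clamped_prediction(self, small_config):
        from sentiwatch.baseline import ModelSpec, fit

        cells = sw.generate_cells(small_config)
        m = fit(cells, ModelSpec("p_pos", ("social",)))
        # force an absurd extrapolation by rigging the coefficients
        m.coefficients[:] = [-0.02, 0.0]
        e = sw.expected_counts(m, cells.head(5))
        assert np.allclose(e, 1e-6 * cells.head(5)["n"].to_numpy())


class TestRanking:
    def test_single_deviation_rank_one(self):
        ranked = rank_deviations(_dev_frame([{}]))
        assert list(ranked["rank"]) == [1]

    def test_permutation_invariance(self):
        frame = _dev_frame(
            [{"observed": o, "city": c} for o, c in
             [(70, "A"), (55, "B"), (62, "C"), (41, "D"), (55, "E")]]
        )
        a = rank_deviations(frame)
        b = rank_deviations(frame.sample(frac=1.0, random_state=5).reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)

    def test_agrees_with_brute_force_sort(self):
        rng = np.random.default_rng(7)
        frame = _dev_frame([{"observed": float(o), "local_hour": int(h)}
                            for o, h in zip(rng.integers(41, 99, 40), rng.integers(0, 24, 40))])
        ranked = rank_deviations(frame)
        assert list(ranked["chi2"]) == sorted(frame["chi2"], reverse=True)
        assert list(ranked["rank"]) == list(range(1, len(frame) + 1))

    def test_outcomes_ranked_separately(self):
        frame = _dev_frame([{"outcome": "negative", "observed": 90},
                            {"outcome": "positive", "observed": 50}])
        ranked = rank_deviations(frame)
        assert set(ranked["rank"]) == {1}


class TestRecurrenceInterval:
    @pytest.fixture()
    def ranked(self):
        # 100 deviations with distinct statistics
        frame = _dev_frame([{"observed": 40.5 + i * 0.55, "local_hour": i % 24,
                             "local_date": f"2017-10-{1 + i // 24:02d}"}
                            for i in range(100)])
        return rank_deviations(frame)

    def test_exceeded_twice_gives_30_days(self, ranked):
        query = ranked.iloc[2]  # exactly 2 strictly larger statistics
        assert recurrence_interval(query["chi2"], ranked, 60) == pytest.approx(30.0)

    def test_exceeded_sixty_times_gives_1_day(self, ranked):
        query = ranked.iloc[60]
        assert recurrence_interval(query["chi2"], ranked, 60) == pytest.approx(1.0)

    def test_top_rank_gives_sentinel(self, ranked):
        assert recurrence_interval(ranked.iloc[0]["chi2"], ranked, 60) == ">60"

    def test_nonincreasing_down_the_ranking(self, ranked):
        annotated = add_recurrence_intervals(ranked, 60)
        numeric = annotated["recurrence_interval"].iloc[1:].astype(float)
        assert (numeric.diff().dropna() <= 1e-12).all()
        assert annotated["recurrence_interval"].iloc[0] == ">60"


class TestMergeEvents:
    def test_single_significant_hour_is_hour_city(self):
        frame = _dev_frame([{"observed": 70}, {"observed": 41, "city": "B"}])
        events = merge_events(rank_deviations(frame), alpha=0.05)
        assert len(events) == 1
        assert events.loc[0, "scope"] == "hour-city"
        assert events.loc[0, "label"] == "A"

    def test_two_hours_same_city_day_merge(self):
        frame = _dev_frame([{"observed": 70, "local_hour": 10},
                            {"observed": 65, "local_hour": 14}])
        events = merge_events(rank_deviations(frame))
        assert len(events) == 1
        assert events.loc[0, "scope"] == "day-city"
        assert events.loc[0, "max_chi2"] == pytest.approx(max(frame["chi2"]))
        assert events.loc[0, "n_members"] == 2

    def test_two_cities_same_country_day_merge(self):
        frame = _dev_frame([{"observed": 70, "city": "A"},
                            {"observed": 65, "city": "B"}])
        events = merge_events(rank_deviations(frame))
        assert len(events) == 1
        assert events.loc[0, "scope"] == "day-country"
        assert events.loc[0, "label"] == "X"

    def test_contiguous_days_merge_to_multiday(self):
        frame = _dev_frame([{"observed": 70, "local_date": "2017-10-01"},
                            {"observed": 66, "local_date": "2017-10-02"},
                            {"observed": 72, "local_date": "2017-10-04"}])
        events = merge_events(rank_deviations(frame))
        assert len(events) == 2
        scopes = set(events["scope"])
        assert scopes == {"multi-day-country", "hour-city"}
        multi = events[events["scope"] == "multi-day-country"].iloc[0]
        assert (multi["date_start"], multi["date_end"]) == ("2017-10-01", "2017-10-02")

    def test_directions_never_merge(self):
        frame = _dev_frame([{"observed": 70}, {"observed": 12, "local_hour": 11}])
        events = merge_events(rank_deviations(frame))
        assert len(events) == 2
        assert set(events["direction"]) == {"excess", "deficit"}

    def test_insignificant_deviations_excluded(self):
        frame = _dev_frame([{"observed": 41}])
        assert merge_events(rank_deviations(frame)).empty


class TestCompareEventLists:
    @pytest.fixture()
    def events(self):
        frame = _dev_frame(
            [{"observed": 70, "city": "A", "country": "X"},
             {"observed": 66, "city": "B", "country": "Y", "local_date": "2017-10-03"},
             {"observed": 62, "city": "C", "country": "Y", "local_date": "2017-10-05"}]
        )
        return merge_events(rank_deviations(frame))

    def test_identical_lists_zero_shifts(self, events):
        report = sw.compare_event_lists(events, events, top_k=10)
        assert (report["rank_shifts"]["shift"] == 0).all()
        assert report["only_a"].empty and report["only_b"].empty
        cc = report["country_counts"]
        assert (cc["count_a"] == cc["count_b"]).all()

    def test_disjoint_lists_all_unique(self, events):
        other = events.copy()
        other["peak_city"] = other["peak_city"] + "_z"
        report = sw.compare_event_lists(events, other, top_k=10)
        assert report["rank_shifts"].empty
        assert len(report["only_a"]) == len(events)
        assert len(report["only_b"]) == len(events)
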