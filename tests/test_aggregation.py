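"""Period aggregation, standard scores and weighted linear aggregation."""

import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wearwell.aggregation import (
    StandardScore,
    aggregate,
    linear_aggregate,
    period_bounds,
    period_label,
    standard_score,
    summaries_to_frame,
)
from wearwell.records import DailyRecord


def _week(person="p1", start=dt.date(2019, 1, 7), days=7, **vals):
    return [
        DailyRecord(person_id=person, date=start + dt.timedelta(days=d), **vals)
        for d in range(days)
    ]


class TestAggregate:
    def test_full_week_mean_steps(self):
        recs = _week(walk_steps=10000.0)
        (s,) = aggregate(recs, "weekly")
        assert s.coverage == 1.0
        assert not s.missing
        assert s.mean_daily_steps == 10000
        assert s.period == "2019-W02"

    def test_sparse_week_flagged_missing(self):
        recs = _week(walk_steps=10000.0)[:3]  # 3 of 7 days
        (s,) = aggregate(recs, "weekly", min_coverage=0.5)
        assert s.missing
        assert s.stats == {}

    def test_weekly_minutes_from_daily_seconds(self):
        recs = _week(physicalactivity_moderate_time=1800.0)
        (s,) = aggregate(recs, "weekly")
        assert s.weekly_moderate_min == pytest.approx(210.0)

    def test_weekly_minutes_unbiased_under_missing_days(self):
        # 5 of 7 days at 1800 s/day still implies 210 weekly minutes
        recs = _week(physicalactivity_moderate_time=1800.0, days=5)
        (s,) = aggregate(recs, "weekly", min_coverage=4 / 7)
        assert s.weekly_moderate_min == pytest.approx(210.0)

    def test_duplicate_records_collapse_and_order_invariance(self):
        recs = _week(walk_steps=8000.0)
        doubled = list(reversed(recs)) + recs
        assert aggregate(doubled, "weekly") == aggregate(recs, "weekly")

    def test_monthly_grouping_and_observed_hr_max(self):
        recs = [
            DailyRecord(
                person_id="p1",
                date=dt.date(2019, 3, d),
                heartrate_max=150.0 + d,
                heartrate_resting=60.0,
            )
            for d in range(1, 32)
        ]
        (s,) = aggregate(recs, "monthly")
        assert s.period == "2019-03"
        assert s.hr_max_observed == 181.0
        assert s.hr_rest_mean == 60.0
        assert s.hr_rest_min == 60.0

    def test_empty_input(self):
        assert aggregate([], "weekly") == []

    def test_export_long_format(self):
        recs = _week(walk_steps=8000.0)
        df = summaries_to_frame(aggregate(recs, "weekly"))
        row = df[df["variable"] == "walk_steps"].iloc[0]
        assert row["mean"] == 8000 and row["total"] == 56000 and row["n_days"] == 7


class TestPeriods:
    def test_iso_week_bounds_monday_to_sunday(self):
        start, end = period_bounds("2019-W02")
        assert start == dt.date(2019, 1, 7) and end == dt.date(2019, 1, 13)
        assert start.weekday() == 0

    def test_month_bounds(self):
        assert period_bounds("2019-02") == (dt.date(2019, 2, 1), dt.date(2019, 2, 28))

    def test_label_round_trip(self):
        d = dt.date(2019, 12, 30)  # ISO week 2020-W01
        assert period_label(d, "weekly") == "2020-W01"
        lo, hi = period_bounds(period_label(d, "weekly"))
        assert lo <= d <= hi


class TestStandardScore:
    def test_mean_centred_definition(self):
        import statistics

        xs = [1.0, 2.0, 3.0, 4.0]
        assert standard_score(2.5, xs).value == pytest.approx(0.0)
        assert standard_score(2.5 + statistics.stdev(xs), xs).value == pytest.approx(1.0)

    def test_median_centred_variant(self):
        s = standard_score(2, [1, 2, 9], center="median")
        assert s.value == pytest.approx(0.0)

    def test_zero_spread_yields_undefined_marker(self):
        s = standard_score(5, [3.0, 3.0, 3.0])
        assert not s.defined and s.value is None

    def test_small_stratum_rejected(self):
        with pytest.raises(ValueError):
            standard_score(1, [1.0])

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=12, unique=True),
        st.floats(-50, 50),
        st.floats(0.1, 10),
        st.floats(-100, 100),
    )
    def test_affine_invariance(self, xs, v, a, b):
        """z-scores are unchanged by x -> a*x + b with a > 0."""
        z1 = standard_score(v, xs).value
        z2 = standard_score(a * v + b, [a * x + b for x in xs]).value
        assert z1 == pytest.approx(z2, rel=1e-6, abs=1e-6)


class TestLinearAggregate:
    def _scores(self, values):
        return [
            StandardScore(f"v{i}", z, "sample", 10) for i, z in enumerate(values)
        ]

    def test_single_score_passthrough(self):
        assert linear_aggregate(self._scores([0.5])) == pytest.approx(0.5)

    def test_symmetric_scores_cancel(self):
        assert linear_aggregate(self._scores([1.0, -1.0])) == pytest.approx(0.0)

    def test_weighted_mean_renormalised(self):
        scores = self._scores([2.0, 0.0, 1.0])
        weights = {"v0": 1, "v1": 1, "v2": 2}
        assert linear_aggregate(scores, weights) == pytest.approx(1.0)

    def test_empty_input_undefined(self):
        assert linear_aggregate([]) is None

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=8))
    def test_result_within_input_range(self, zs):
        out = linear_aggregate(self._scores(zs))
        assert min(zs) - 1e-9 <= out <= max(zs) + 1e-9
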