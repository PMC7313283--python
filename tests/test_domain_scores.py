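"""Domain scorers against the published band tables and brute-force
interval oracles."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (
    SLEEP_TABLE,
    activity_oracle,
    sleep_oracle,
    vo2max_oracle,
    walking_oracle,
)
from wearwell.records import Gender, PersonProfile
from wearwell.scores import (
    ActivitySummary,
    estimate_vo2max,
    score_physical_activity,
    score_sleep,
    score_vo2max,
    score_walking,
)


class TestWalking:
    @pytest.mark.parametrize(
        "steps, score",
        [
            (13000, 5), (12500, 5),  # highly active: 12,500 or more
            (10000, 4), (12499, 4),  # active
            (7500, 3), (9999, 3),    # somewhat active
            (5000, 2), (7499, 2),    # lowly active
            (0, 1), (4999, 1),       # sedentary
        ],
    )
    def test_published_bands(self, steps, score):
        assert score_walking(steps) == score

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            score_walking(-1)


class TestPhysicalActivity:
    @pytest.mark.parametrize(
        "moderate, vigorous, score",
        [
            (150, 0, 4), (0, 75, 4),   # meets aerobic guidelines
            (60, 0, 3), (0, 30, 3),    # certain activity
            (30, 0, 2), (0, 15, 2),    # low activity
            (0, 0, 1), (29, 0, 1), (0, 14, 1),  # inactive
            (60, 10, 3),               # equivalent combination: m = 80
            (100, 25, 4),              # m = 150 at the guideline edge
        ],
    )
    def test_published_bands_and_equivalence(self, moderate, vigorous, score):
        assert score_physical_activity(ActivitySummary(moderate, vigorous)) == score

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ActivitySummary(-1, 0)


class TestSleep:
    @pytest.mark.parametrize(
        "age, hours, score",
        [
            (30, 8, 2.0),     # adults recommended 7-9 h
            (30, 6, 1.75),    # adults "considered appropriate" 6 h
            (30, 5, 1.0),     # adults under 6 h not recommended
            (30, 10, 1.75),   # adults appropriate 10 h
            (30, 11, 1.0),    # adults above 10 h not recommended
            (70, 10, 1.0),    # older adults: more than 9 h not recommended
            (70, 7.5, 2.0),   # older adults recommended 7-8 h
            (70, 5, 1.75),    # older adults appropriate 5-6 h
            (20, 10.5, 1.75), # young adults appropriate 10-11 h
            (16, 9, 2.0),     # teenagers recommended 8-10 h
            (10, 12, 1.75),   # school-aged appropriate 12 h
            (4, 13.5, 1.75),  # preschoolers appropriate up to 14 h
            (2, 12, 2.0),     # toddlers recommended 11-14 h
        ],
    )
    def test_published_age_bands(self, age, hours, score, norms):
        assert score_sleep(age, hours, norms.sleep) == score

    def test_ages_above_oldest_bracket_use_older_adults(self, norms):
        assert score_sleep(95, 7.5, norms.sleep) == 2.0

    def test_invalid_duration_rejected(self, norms):
        with pytest.raises(ValueError):
            score_sleep(30, -1, norms.sleep)
        with pytest.raises(ValueError):
            score_sleep(30, 25, norms.sleep)

    def test_range_is_exactly_three_values(self, norms, rng):
        seen = {
            score_sleep(float(a), float(h), norms.sleep)
            for a, h in zip(rng.uniform(0, 100, 3000), rng.uniform(0, 24, 3000))
        }
        assert seen == {1.0, 1.75, 2.0}

    @pytest.mark.parametrize("row", SLEEP_TABLE, ids=lambda r: f"age{r[0][0]}")
    def test_unimodal_in_duration(self, row, norms):
        """The score rises to 2 inside the recommended band then falls —
        never rises again after a fall."""
        (a_lo, _), _, _ = row
        scores = [
            score_sleep(a_lo, h / 4, norms.sleep) for h in range(0, 24 * 4 + 1)
        ]
        falls_seen = False
        for prev, cur in zip(scores, scores[1:]):
            if cur < prev:
                falls_seen = True
            assert not (falls_seen and cur > prev), "score rose again after falling"


class TestVo2max:
    @pytest.mark.parametrize(
        "hr_max, hr_rest, expected",
        [(60, 60, 15.3), (200, 50, 61.2), (190, 60, 48.45)],
    )
    def test_formula(self, hr_max, hr_rest, expected):
        assert estimate_vo2max(hr_max, hr_rest) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rest_rejected_but_inverted_ratio_warns(self):
        with pytest.raises(ValueError):
            estimate_vo2max(180, 0)
        with pytest.warns(UserWarning):
            assert estimate_vo2max(50, 100) == pytest.approx(7.65)

    def test_floor_and_ceiling_of_scale(self, norms):
        p = PersonProfile("p", 30, Gender.MALE)
        assert score_vo2max(1.0, p, norms.vo2max) == 1
        assert score_vo2max(200.0, p, norms.vo2max) == 7

    def test_score_at_cut_points_matches_closed_lower_bound_rule(self, norms):
        for gender in (Gender.MALE, Gender.FEMALE):
            for age in (20, 30, 40, 50, 60, 70):
                p = PersonProfile("p", age, gender)
                cuts = norms.vo2max.cuts_for(gender, age)
                for k, c in enumerate(cuts[:5], start=2):
                    assert score_vo2max(c, p, norms.vo2max) == k
                    assert score_vo2max(c - 1e-9, p, norms.vo2max) == k - 1
                # topmost cut is the inclusive upper bound of category 6
                assert score_vo2max(cuts[5], p, norms.vo2max) == 6
                assert score_vo2max(cuts[5] + 1e-9, p, norms.vo2max) == 7

    def test_unspecified_gender_uses_mean_cut_points(self, norms):
        cuts = norms.vo2max.cuts_for(Gender.UNSPECIFIED, 30)
        m = norms.vo2max.cuts_for(Gender.MALE, 30)
        f = norms.vo2max.cuts_for(Gender.FEMALE, 30)
        assert cuts == [(a + b) / 2 for a, b in zip(m, f)]
        assert score_vo2max(40.0, PersonProfile("p", 30), norms.vo2max) in range(1, 8)

    def test_age_outside_brackets_clamps(self, norms):
        assert norms.vo2max.cuts_for(Gender.MALE, 6) == norms.vo2max.cuts_for(
            Gender.MALE, 18
        )
        assert norms.vo2max.cuts_for(Gender.MALE, 90) == norms.vo2max.cuts_for(
            Gender.MALE, 75
        )


class TestOracleEquivalence:
    """Each scorer agrees with a brute-force interval-membership oracle
    on thousands of random inputs."""

    def test_walking(self, rng):
        for steps in rng.uniform(0, 20000, 10_000):
            assert score_walking(steps) == walking_oracle(steps)

    def test_activity(self, rng):
        mods = rng.uniform(0, 250, 10_000)
        vigs = rng.uniform(0, 120, 10_000)
        for m, v in zip(mods, vigs):
            assert score_physical_activity(ActivitySummary(m, v)) == activity_oracle(m, v)

    def test_sleep(self, norms, rng):
        ages = rng.uniform(0, 100, 10_000)
        hours = rng.uniform(0, 24, 10_000)
        for a, h in zip(ages, hours):
            assert score_sleep(a, h, norms.sleep) == sleep_oracle(a, h)

    def test_vo2max(self, norms, rng):
        genders = [Gender.MALE, Gender.FEMALE]
        for _ in range(50):
            gender = genders[int(rng.integers(2))]
            age = int(rng.integers(18, 76))
            p = PersonProfile("p", age, gender)
            cuts = norms.vo2max.cuts_for(gender, age)
            for v in rng.uniform(10, 70, 200):
                assert score_vo2max(v, p, norms.vo2max) == vo2max_oracle(v, cuts)


class TestMonotonicity:
    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 20000), st.floats(0, 20000))
    def test_walking_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert score_walking(lo) <= score_walking(hi)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(0, 300), st.floats(0, 300), st.floats(0, 100))
    def test_activity_monotone_in_moderate_minutes(self, a, b, vig):
        lo, hi = sorted((a, b))
        assert score_physical_activity(
            ActivitySummary(lo, vig)
        ) <= score_physical_activity(ActivitySummary(hi, vig))

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(5, 70), st.floats(5, 70), st.integers(18, 75))
    def test_vo2max_monotone_within_cell(self, a, b, age):
        lo, hi = sorted((a, b))
        p = PersonProfile("p", age, Gender.FEMALE)
        assert score_vo2max(lo, p) <= score_vo2max(hi, p)
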