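"""Domain scoring rules for the four physical well-being dimensions.

Each scorer is a pure threshold/formula function:

* walking — mean daily step count banded on the sedentary..highly-active
  scale (1-5);
* physical activity/exercise — weekly moderate-equivalent minutes banded
  on the inactive..meets-aerobic-guidelines scale (1-4), where one
  vigorous minute counts as two moderate minutes;
* sleep — mean daily sleep duration against the National Sleep
  Foundation age bands, scored 2 (recommended), 1.75 (mildly risky) or
  1 (not recommended);
* cardio-respiratory fitness — a non-exercise VO2max estimate
  ``(hr_max / hr_rest) * 15.3`` categorised 1 (very low) .. 7 (elite)
  against gender- and age-stratified norms.

The sleep and VO2max norm tables ship as an editable YAML reference file
(:data:`DEFAULT_NORMS_PATH`) and are validated on load.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .records import Gender, PersonProfile

__all__ = [
    "ActivitySummary",
    "DomainIndices",
    "SleepNormTable",
    "Vo2maxNormTable",
    "NormTables",
    "DEFAULT_NORMS_PATH",
    "load_norms",
    "score_walking",
    "score_physical_activity",
    "score_sleep",
    "estimate_vo2max",
    "score_vo2max",
    "VIGOROUS_EQUIVALENCE",
    "VO2MAX_FACTOR",
    "SLEEP_SCORES",
]

#: One vigorous minute is equivalent to two moderate minutes, consistent
#: with the paired guideline thresholds (150 moderate or 75 vigorous,
#: 60 or 30, 30 or 15).
VIGOROUS_EQUIVALENCE = 2.0

#: Constant of the non-exercise VO2max estimate, mL/(kg*min).
VO2MAX_FACTOR = 15.3

#: Scores attached to the three sleep-duration bands.
SLEEP_SCORES = {"recommended": 2.0, "appropriate": 1.75, "not_recommended": 1.0}

DEFAULT_NORMS_PATH = Path(str(resources.files("wearwell") / "data" / "norms.yaml"))


@dataclass(frozen=True)
class ActivitySummary:
    """Weekly minutes of moderate and vigorous physical activity."""

    weekly_moderate_min: float
    weekly_vigorous_min: float

    def __post_init__(self) -> None:
        if self.weekly_moderate_min < 0 or self.weekly_vigorous_min < 0:
            raise ValueError("activity minutes must be >= 0")

    @property
    def moderate_equivalent_min(self) -> float:
        return self.weekly_moderate_min + VIGOROUS_EQUIVALENCE * self.weekly_vigorous_min


@dataclass(frozen=True)
class DomainIndices:
    """The four domain scores for one person-period.

    ``None`` marks a domain that could not be scored (insufficient data);
    the composite refuses partial input, so any ``None`` propagates to a
    missing composite point.
    """

    person_id: str
    period: str
    walking: float | None = None  # 1..5
    activity: float | None = None  # 1..4
    sleep: float | None = None  # {1, 1.75, 2}
    cardio: float | None = None  # 1..7

    @property
    def complete(self) -> bool:
        return None not in (self.walking, self.activity, self.sleep, self.cardio)

    def as_tuple(self) -> tuple[float, float, float, float]:
        if not self.complete:
            raise ValueError("incomplete indices")
        return (self.walking, self.activity, self.sleep, self.cardio)


@dataclass(frozen=True)
class _SleepCategory:
    name: str
    age_min: float
    age_max: float | None  # exclusive; None = open-ended
    recommended: tuple[float, float]
    appropriate: tuple[float, float]


class SleepNormTable:
    """Age-stratified recommended / appropriate sleep-duration bands."""

    def __init__(self, categories: list[_SleepCategory]):
        if not categories:
            raise ValueError("empty sleep norm table")
        self.categories = sorted(categories, key=lambda c: c.age_min)
        for c in self.categories:
            rl, rh = c.recommended
            al, ah = c.appropriate
            if not (0 < al <= rl < rh <= ah <= 24):
                raise ValueError(
                    f"sleep bands for {c.name} must nest: "
                    f"appropriate {c.appropriate} around recommended {c.recommended}"
                )
        prev_max = 0.0
        for c in self.categories:
            if c.age_min != prev_max:
                raise ValueError("sleep age categories must tile [0, inf)")
            prev_max = c.age_max if c.age_max is not None else float("inf")
        if prev_max != float("inf"):
            raise ValueError("last sleep category must be open-ended")

    def category_for_age(self, age: float) -> _SleepCategory:
        if age < 0:
            raise ValueError("age must be >= 0")
        for c in self.categories:
            if c.age_max is None or age < c.age_max:
                return c
        raise AssertionError("unreachable: last category is open-ended")


class Vo2maxNormTable:
    """Gender- and age-bracketed VO2max category cut-points (scores 1-7)."""

    def __init__(self, cells: dict[str, list[dict]]):
        self.cells: dict[str, list[tuple[float, float, list[float]]]] = {}
        for gender, brackets in cells.items():
            rows = []
            for b in sorted(brackets, key=lambda r: r["age_min"]):
                cuts = [float(c) for c in b["cuts"]]
                if len(cuts) != 6 or any(
                    a >= b_ for a, b_ in zip(cuts, cuts[1:])
                ):
                    raise ValueError(
                        f"{gender} {b['age_min']}-{b['age_max']}: "
                        "need 6 strictly increasing cut-points"
                    )
                rows.append((float(b["age_min"]), float(b["age_max"]), cuts))
            if not rows:
                raise ValueError(f"no brackets for gender {gender!r}")
            self.cells[gender] = rows
        if set(self.cells) != {"male", "female"}:
            raise ValueError("vo2max norms need exactly male and female strata")

    def cuts_for(self, gender: Gender, age: float) -> list[float]:
        """Cut-points for a profile; unspecified gender uses the mean of
        the male and female cut-points, out-of-range ages clamp to the
        nearest bracket."""
        if gender is Gender.UNSPECIFIED:
            m = self.cuts_for(Gender.MALE, age)
            f = self.cuts_for(Gender.FEMALE, age)
            return [(a + b) / 2 for a, b in zip(m, f)]
        rows = self.cells[gender.value]
        for lo, hi, cuts in rows:
            if lo <= age <= hi:
                return cuts
        return rows[0][2] if age < rows[0][0] else rows[-1][2]


@dataclass(frozen=True)
class NormTables:
    sleep: SleepNormTable
    vo2max: Vo2maxNormTable


def load_norms(path: str | Path | None = None) -> NormTables:
    """Load and validate the norms reference file (YAML)."""
    p = Path(path) if path is not None else DEFAULT_NORMS_PATH
    with open(p) as fh:
        raw = yaml.safe_load(fh)
    sleep = SleepNormTable(
        [
            _SleepCategory(
                name=row["name"],
                age_min=float(row["age_min"]),
                age_max=None if row["age_max"] is None else float(row["age_max"]),
                recommended=tuple(map(float, row["recommended"])),
                appropriate=tuple(map(float, row["appropriate"])),
            )
            for row in raw["sleep"]
        ]
    )
    return NormTables(sleep=sleep, vo2max=Vo2maxNormTable(raw["vo2max"]))


def score_walking(mean_daily_steps: float) -> int:
    """Band a mean daily step count on the 1-5 walking-activity scale.

    >= 12,500 steps/day is highly active (5); 10,000-12,499 active (4);
    7,500-9,999 somewhat active (3); 5,000-7,499 lowly active (2);
    under 5,000 sedentary (1).
    """
    if mean_daily_steps < 0:
        raise ValueError("mean_daily_steps must be >= 0")
    for cut, score in ((12500, 5), (10000, 4), (7500, 3), (5000, 2)):
        if mean_daily_steps >= cut:
            return score
    return 1


def score_physical_activity(summary: ActivitySummary) -> int:
    """Band weekly activity on the 1-4 exercise-guideline scale.

    Uses moderate-equivalent minutes ``m = moderate + 2 * vigorous``:
    m >= 150 meets aerobic guidelines (4); 60-149 certain activity (3);
    30-59 low activity (2); under 30 inactive (1).
    """
    m = summary.moderate_equivalent_min
    for cut, score in ((150, 4), (60, 3), (30, 2)):
        if m >= cut:
            return score
    return 1


def score_sleep(
    age: float, mean_daily_sleep_h: float, table: SleepNormTable | None = None
) -> float:
    """Score mean daily sleep duration for a given age: 2 in the
    recommended band, 1.75 in the mildly-risky ("may be appropriate")
    envelope, 1 outside it."""
    if not 0 <= mean_daily_sleep_h <= 24:
        raise ValueError("mean_daily_sleep_h must be in [0, 24]")
    if table is None:
        table = _default_norms().sleep
    cat = table.category_for_age(age)
    rl, rh = cat.recommended
    al, ah = cat.appropriate
    if rl <= mean_daily_sleep_h <= rh:
        return SLEEP_SCORES["recommended"]
    if al <= mean_daily_sleep_h <= ah:
        return SLEEP_SCORES["appropriate"]
    return SLEEP_SCORES["not_recommended"]


def estimate_vo2max(hr_max: float, hr_rest: float) -> float:
    """Non-exercise VO2max estimate ``(hr_max / hr_rest) * 15.3`` in
    mL/(kg*min)."""
    if hr_rest <= 0:
        raise ValueError("hr_rest must be positive")
    if hr_max < hr_rest:
        warnings.warn(
            f"hr_max={hr_max} below hr_rest={hr_rest}; estimate still computed",
            stacklevel=2,
        )
    return hr_max / hr_rest * VO2MAX_FACTOR


def score_vo2max(
    vo2max: float, profile: PersonProfile, norms: Vo2maxNormTable | None = None
) -> int:
    """Categorise a VO2max estimate 1 (very low) .. 7 (elite) against the
    gender/age norms.  Values at a cut-point belong to the higher
    category, except the topmost cut which is the inclusive upper bound
    of category 6."""
    if norms is None:
        norms = _default_norms().vo2max
    cuts = norms.cuts_for(profile.gender, profile.age)
    score = 1 + sum(vo2max >= c for c in cuts[:5])
    if vo2max > cuts[5]:
        score += 1
    return score


_NORMS_CACHE: NormTables | None = None


def _default_norms() -> NormTables:
    global _NORMS_CACHE
    if _NORMS_CACHE is None:
        _NORMS_CACHE = load_norms()
    return _NORMS_CACHE
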