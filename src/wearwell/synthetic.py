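"""Seeded synthetic cohort generator.

Emulates the statistical structure the well-being model assumes: each
person carries a latent well-being level L on [0, 1] that monotonically
drives their daily step counts, activity minutes, sleep duration and
resting heart rate, as well as their questionnaire answers.  The
generator makes no claim of physiological realism beyond those monotone
links — its job is to exercise the whole pipeline, span all scoring
bands across a cohort, and make latent-to-measured correlations
recoverable end to end.

Distributional choices (documented in the methods note): negative
binomial daily steps (right-skewed counts), zero-inflated gamma activity
seconds, truncated-normal sleep hours and resting heart rate, and
discretised noisy-monotone questionnaire items.  All randomness flows
from one ``numpy`` generator seeded by the config.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .questionnaires import Eq5Response, EssResponse, write_responses
from .records import (
    DailyRecord,
    Gender,
    PersonProfile,
    write_daily_records,
    write_profiles,
)

__all__ = ["CohortConfig", "Cohort", "generate", "write_cohort", "worked_example_fixture"]


@dataclass(frozen=True)
class LinkStrengths:
    """How strongly the latent level drives each measured domain, each
    in [0, 1]; 0 severs the link (population-average behaviour)."""

    steps: float = 1.0
    activity: float = 1.0
    sleep: float = 1.0
    resting_hr: float = 1.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0 <= v <= 1:
                raise ValueError(f"link strength {f.name}={v} outside [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    n_persons: int = 50
    start: _dt.date = _dt.date(2019, 1, 1)
    n_days: int = 180
    seed: int = 0
    latent_mean: float = 0.55
    latent_sd: float = 0.20
    links: LinkStrengths = field(default_factory=LinkStrengths)
    missingness: float = 0.10
    questionnaire_noise_sd: float = 0.15
    step_overestimation: float = 1.0

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.latent_sd < 0 or self.questionnaire_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.missingness <= 1:
            raise ValueError("missingness must be in [0, 1]")
        if self.step_overestimation <= 0:
            raise ValueError("step_overestimation must be > 0")


class Cohort(NamedTuple):
    profiles: list[PersonProfile]
    records: list[DailyRecord]
    ess: list[EssResponse]
    eq5: list[Eq5Response]
    #: per-person latent well-being level on [0, 1]; the ground truth the
    #: pipeline is expected to recover (not written to any output file)
    latents: dict[str, float] = {}


def _effective(latent: float, strength: float) -> float:
    """Interpolate between the cohort midpoint and the person's latent
    level by link strength."""
    return strength * latent + (1 - strength) * 0.5


def _neg_binomial(rng: np.random.Generator, mean: float, k: float = 12.0) -> int:
    p = k / (k + mean)
    return int(rng.negative_binomial(k, p))


def _likert(rng: np.random.Generator, latent: float, noise_sd: float) -> float:
    return float(np.clip(latent + rng.normal(0, noise_sd), 0, 1))


def generate(config: CohortConfig) -> Cohort:
    """Generate a cohort: profiles, multi-month daily records and
    latent-correlated ESS/EQ5 responses, reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    profiles: list[PersonProfile] = []
    records: list[DailyRecord] = []
    ess: list[EssResponse] = []
    eq5: list[Eq5Response] = []
    latents: dict[str, float] = {}
    days = [config.start + _dt.timedelta(days=d) for d in range(config.n_days)]

    for i in range(config.n_persons):
        pid = f"sim{i:04d}"
        age = int(rng.integers(20, 76))
        gender = Gender.MALE if rng.random() < 0.5 else Gender.FEMALE
        profiles.append(PersonProfile(pid, age, gender))
        latent = float(np.clip(rng.normal(config.latent_mean, config.latent_sd), 0, 1))
        latents[pid] = latent

        l_steps = _effective(latent, config.links.steps)
        l_act = _effective(latent, config.links.activity)
        l_sleep = _effective(latent, config.links.sleep)
        l_hr = _effective(latent, config.links.resting_hr)

        mean_steps = 1500 + 13500 * l_steps
        # weekly moderate-equivalent minutes ~ 380 * l^2.2 spans the four
        # guideline bands over a latent range of [0, 1]
        daily_moderate_s = 300 * 60 / 7 * l_act**2.2
        daily_vigorous_s = 40 * 60 / 7 * l_act**2.2
        sleep_mean_h = 5.3 + 3.4 * l_sleep
        rest_hr_mean = 78 - 24 * l_hr
        hr_max_mean = min(220 - age - 8, 240)

        for day in days:
            if rng.random() < config.missingness:
                continue
            steps = _neg_binomial(rng, mean_steps) * config.step_overestimation
            moderate = (
                0.0
                if rng.random() < 0.25 or daily_moderate_s <= 0
                else float(rng.gamma(1.2, daily_moderate_s / 1.2 / 0.75))
            )
            vigorous = (
                0.0
                if rng.random() < 0.60 or daily_vigorous_s <= 0
                else float(rng.gamma(1.2, daily_vigorous_s / 1.2 / 0.40))
            )
            sleep_h = float(np.clip(rng.normal(sleep_mean_h, 0.5), 2.5, 13))
            rest_hr = float(np.clip(rng.normal(rest_hr_mean, 1.5), 40, 120))
            rec = {
                "person_id": pid,
                "date": day,
                "walk_steps": float(round(steps)),
                "walk_distance": float(round(steps * 0.75, 1)),
                "physicalactivity_moderate_time": round(moderate, 1),
                "physicalactivity_intense_time": round(vigorous, 1),
                "sleep_time": round(sleep_h * 3600, 0),
                "sleep_asleep_time": round(sleep_h * 3600 * 0.92, 0),
                "heartrate_resting": round(rest_hr, 1),
            }
            if rng.random() < 0.5:
                rec["heartrate_max"] = float(
                    np.clip(round(rng.normal(hr_max_mean, 5), 1), 80, 249)
                )
            records.append(DailyRecord(**rec))

        # 1-3 questionnaire fillings per person, most fill once
        n_fill = int(rng.choice([1, 1, 1, 2, 2, 3]))
        fill_days = sorted(
            int(d) for d in rng.choice(config.n_days, size=n_fill, replace=False)
        )
        for d in fill_days:
            ts = _dt.datetime.combine(days[d], _dt.time(12, 0))
            items = tuple(
                int(round(4 * _likert(rng, latent, config.questionnaire_noise_sd)))
                for _ in range(15)
            )
            ess.append(EssResponse(pid, ts, items))
            dims = tuple(
                1 + int(round(4 * _likert(rng, latent, config.questionnaire_noise_sd)))
                for _ in range(5)
            )
            hsa = round(100 * _likert(rng, latent, config.questionnaire_noise_sd), 0)
            eq5.append(Eq5Response(pid, ts, dims, hsa))

    return Cohort(profiles, records, ess, eq5, latents)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write the four cohort files in the CSV dialects the readers
    consume; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "profiles": out / "profiles.csv",
        "records": out / "daily_records.csv",
        "ess": out / "responses_ess.csv",
        "eq5": out / "responses_eq5.csv",
    }
    write_profiles(cohort.profiles, paths["profiles"])
    write_daily_records(cohort.records, paths["records"])
    write_responses(cohort.ess, paths["ess"])
    write_responses(cohort.eq5, paths["eq5"])
    return paths


# ---------------------------------------------------------------------------
# Hand-written golden fixture: four persons, eight full ISO weeks, each
# landing in a known scoring category per domain.

_FIXTURE_START = _dt.date(2019, 1, 7)  # a Monday; 56 days = 8 ISO weeks
_FIXTURE_DAYS = 56

_FIXTURE_PEOPLE: list[dict] = [
    # highly active, meets guidelines, recommended sleep, elite fitness
    dict(person_id="gold_a", age=30, gender=Gender.MALE, steps=13000,
         moderate_s=1800.0, sleep_h=8.0, rest_hr=50.0, hr_max=190.0),
    # lowly active walker, inactive (20 moderate min/week), good sleep
    dict(person_id="gold_b", age=30, gender=Gender.FEMALE, steps=6000,
         moderate_s=1200.0 / 7, sleep_h=7.5, rest_hr=70.0, hr_max=None),
    # somewhat active, certain activity, mildly risky sleep
    dict(person_id="gold_c", age=30, gender=Gender.MALE, steps=8000,
         moderate_s=900.0, sleep_h=6.0, rest_hr=65.0, hr_max=None),
    # sedentary older adult, inactive, oversleeping, low fitness
    dict(person_id="gold_d", age=70, gender=Gender.MALE, steps=3000,
         moderate_s=0.0, sleep_h=10.0, rest_hr=90.0, hr_max=None),
]

#: Expected per-week domain indices of the golden fixture (I_w, I_p, I_s, I_c).
WORKED_EXAMPLE_INDICES: dict[str, tuple[float, float, float, float]] = {
    "gold_a": (5, 4, 2.0, 7),
    "gold_b": (2, 1, 2.0, 5),
    "gold_c": (3, 3, 1.75, 5),
    "gold_d": (1, 1, 1.0, 3),
}


def worked_example_fixture() -> Cohort:
    """A fixed 4-person, 8-week cohort with constant daily behaviour,
    every person in a known band per domain (see
    :data:`WORKED_EXAMPLE_INDICES`); the golden end-to-end fixture."""
    profiles = []
    records = []
    ess: list[EssResponse] = []
    eq5: list[Eq5Response] = []
    days = [_FIXTURE_START + _dt.timedelta(days=d) for d in range(_FIXTURE_DAYS)]
    quality = {"gold_a": 4, "gold_b": 3, "gold_c": 2, "gold_d": 1}
    for spec in _FIXTURE_PEOPLE:
        profiles.append(
            PersonProfile(spec["person_id"], spec["age"], spec["gender"])
        )
        for day in days:
            rec = {
                "person_id": spec["person_id"],
                "date": day,
                "walk_steps": float(spec["steps"]),
                "physicalactivity_moderate_time": spec["moderate_s"],
                "physicalactivity_intense_time": 0.0,
                "sleep_time": spec["sleep_h"] * 3600,
                "heartrate_resting": spec["rest_hr"],
            }
            if spec["hr_max"] is not None:
                rec["heartrate_max"] = spec["hr_max"]
            records.append(DailyRecord(**rec))
        ts = _dt.datetime.combine(days[28], _dt.time(9, 0))
        q = quality[spec["person_id"]]
        ess.append(EssResponse(spec["person_id"], ts, (q,) * 15))
        eq5.append(Eq5Response(spec["person_id"], ts, (q + 1,) * 5, 25.0 * q))
    latents = {p: 0.2 * q for p, q in quality.items()}
    return Cohort(profiles, records, ess, eq5, latents)
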