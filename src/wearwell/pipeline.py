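"""End-to-end scoring: daily records -> period summaries -> domain
indices -> composite series."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from .aggregation import PeriodSummary, aggregate
from .composite import (
    CompositePoint,
    CompositeWeights,
    DEFAULT_WEIGHTS,
    composite_series,
)
from .records import DailyRecord, PersonProfile, estimate_hr_max
from .scores import (
    ActivitySummary,
    DomainIndices,
    NormTables,
    estimate_vo2max,
    load_norms,
    score_sleep,
    score_vo2max,
    score_walking,
    score_physical_activity,
)

__all__ = ["compute_domain_indices", "score_cohort", "indices_to_frame"]


def compute_domain_indices(
    summaries: Sequence[PeriodSummary],
    profiles: Iterable[PersonProfile],
    norms: NormTables | None = None,
    rest_hr_stat: Literal["mean", "min"] = "mean",
) -> list[DomainIndices]:
    """Score each non-missing period summary on the four domains.

    A domain whose inputs are absent stays None.  For the activity
    domain, an intensity the device never reported over a covered
    period counts as zero minutes provided the other intensity was
    reported — absence of both leaves the domain unscored.  The
    cardio domain uses the period's device-observed maximum heart rate
    when present, else 220 - age, over the mean (or, per
    ``rest_hr_stat``, minimum) resting heart rate.
    """
    if norms is None:
        norms = load_norms()
    by_id = {p.person_id: p for p in profiles}
    out: list[DomainIndices] = []
    for s in summaries:
        profile = by_id.get(s.person_id)
        if profile is None:
            raise ValueError(f"no profile for person {s.person_id!r}")
        walking = activity = sleep = cardio = None
        if not s.missing:
            if s.mean_daily_steps is not None:
                walking = float(score_walking(s.mean_daily_steps))
            mod, vig = s.weekly_moderate_min, s.weekly_vigorous_min
            if mod is not None or vig is not None:
                activity = float(
                    score_physical_activity(
                        ActivitySummary(mod or 0.0, vig or 0.0)
                    )
                )
            if s.mean_sleep_h is not None:
                sleep = score_sleep(profile.age, s.mean_sleep_h, norms.sleep)
            rest = s.hr_rest_mean if rest_hr_stat == "mean" else s.hr_rest_min
            if rest is not None and rest > 0:
                hr_max = estimate_hr_max(profile, s.hr_max_observed)
                vo2 = estimate_vo2max(hr_max, rest)
                cardio = float(score_vo2max(vo2, profile, norms.vo2max))
        out.append(
            DomainIndices(
                person_id=s.person_id,
                period=s.period,
                walking=walking,
                activity=activity,
                sleep=sleep,
                cardio=cardio,
            )
        )
    return out


def indices_to_frame(indices: Sequence[DomainIndices]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": ix.person_id,
                "period": ix.period,
                "I_w": ix.walking,
                "I_p": ix.activity,
                "I_s": ix.sleep,
                "I_c": ix.cardio,
            }
            for ix in indices
        ],
        columns=["person_id", "period", "I_w", "I_p", "I_s", "I_c"],
    )


def score_cohort(
    records: Iterable[DailyRecord],
    profiles: Sequence[PersonProfile],
    period_kind: Literal["weekly", "monthly"] = "monthly",
    min_coverage: float | None = None,
    norms: NormTables | None = None,
    weights: CompositeWeights = DEFAULT_WEIGHTS,
    root_mode: Literal["fixed_4", "weight_sum"] = "fixed_4",
    rest_hr_stat: Literal["mean", "min"] = "mean",
) -> tuple[list[DomainIndices], list[CompositePoint]]:
    """Run the full scoring pipeline and return (indices, composites)."""
    summaries = aggregate(records, period_kind, min_coverage)
    indices = compute_domain_indices(summaries, profiles, norms, rest_hr_stat)
    points = composite_series(indices, weights, root_mode)
    return indices, points
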