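"""Weekly/monthly aggregation of daily records and standard scores.

Daily measurements are summarised per person and calendar period (ISO
week Monday-Sunday, or calendar month) into per-variable statistics plus
the derived quantities the domain scorers consume: mean daily steps,
weekly moderate/vigorous activity minutes, mean sleep hours and the
resting/maximum heart-rate summaries.  Periods whose fraction of days
with data falls below a coverage threshold are flagged missing rather
than scored on thin evidence.

The module also provides the complementary data-driven primitives: a
standard score of a measurement against a norm stratum (with selectable
centre and spread statistics) and a weighted linear aggregation of such
scores.
"""

from __future__ import annotations

import calendar
import datetime as _dt
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .records import DAILY_VARIABLES, DailyRecord, records_to_frame

__all__ = [
    "PeriodSummary",
    "StandardScore",
    "DEFAULT_MIN_COVERAGE",
    "period_label",
    "period_bounds",
    "aggregate",
    "summaries_to_frame",
    "write_summaries",
    "standard_score",
    "linear_aggregate",
]

#: Default minimum fraction of days with data for a period to be scored.
DEFAULT_MIN_COVERAGE = {"weekly": 4 / 7, "monthly": 15 / 31}


def period_label(day: _dt.date, period_kind: str) -> str:
    """Canonical period label: ``2019-W09`` (ISO week) or ``2019-03``."""
    if period_kind == "weekly":
        iso = day.isocalendar()
        return f"{iso.year}-W{iso.week:02d}"
    if period_kind == "monthly":
        return f"{day.year}-{day.month:02d}"
    raise ValueError(f"unknown period kind {period_kind!r}")


def period_bounds(label: str) -> tuple[_dt.date, _dt.date]:
    """First and last calendar day of a period label."""
    if "-W" in label:
        year, week = label.split("-W")
        start = _dt.date.fromisocalendar(int(year), int(week), 1)
        return start, start + _dt.timedelta(days=6)
    year, month = map(int, label.split("-"))
    last = calendar.monthrange(year, month)[1]
    return _dt.date(year, month, 1), _dt.date(year, month, last)


@dataclass
class PeriodSummary:
    """Per-person, per-period statistics over the daily measurements."""

    person_id: str
    period: str
    period_kind: str
    coverage: float
    missing: bool
    #: variable -> (mean over contributing days, total, n contributing days)
    stats: dict[str, tuple[float, float, int]] = field(default_factory=dict)

    def mean(self, variable: str) -> float | None:
        s = self.stats.get(variable)
        return None if s is None else s[0]

    def total(self, variable: str) -> float | None:
        s = self.stats.get(variable)
        return None if s is None else s[1]

    # -- derived quantities consumed by the domain scorers ---------------
    @property
    def mean_daily_steps(self) -> float | None:
        return self.mean("walk_steps")

    def _weekly_minutes(self, variable: str) -> float | None:
        m = self.mean(variable)
        return None if m is None else m * 7 / 60

    @property
    def weekly_moderate_min(self) -> float | None:
        """Mean daily moderate-activity seconds scaled to minutes per
        week; for a fully covered ISO week this equals the summed weekly
        minutes, and it stays unbiased when days are missing."""
        return self._weekly_minutes("physicalactivity_moderate_time")

    @property
    def weekly_vigorous_min(self) -> float | None:
        return self._weekly_minutes("physicalactivity_intense_time")

    @property
    def mean_sleep_h(self) -> float | None:
        m = self.mean("sleep_time")
        return None if m is None else m / 3600

    @property
    def hr_rest_mean(self) -> float | None:
        return self.mean("heartrate_resting")

    @property
    def hr_rest_min(self) -> float | None:
        s = self.stats.get("heartrate_resting_min")
        return None if s is None else s[0]

    @property
    def hr_max_observed(self) -> float | None:
        s = self.stats.get("heartrate_max_observed")
        return None if s is None else s[0]


def aggregate(
    records: Iterable[DailyRecord],
    period_kind: Literal["weekly", "monthly"] = "monthly",
    min_coverage: float | None = None,
) -> list[PeriodSummary]:
    """Summarise daily records into per-person period summaries.

    Every measured variable present in a period contributes a
    (mean, total, count-of-days) triple.  Coverage is the fraction of
    calendar days in the period with at least one measurement; periods
    under ``min_coverage`` are emitted flagged missing (missingness is
    data, not an error).  Duplicated records collapse to one person-day.
    """
    if min_coverage is None:
        min_coverage = DEFAULT_MIN_COVERAGE[period_kind]
    if not 0 < min_coverage <= 1:
        raise ValueError("min_coverage must be in (0, 1]")
    records = list(records)
    if not records:
        return []
    df = records_to_frame(records)
    df = df.drop_duplicates(subset=["person_id", "date"])
    df["period"] = [period_label(d, period_kind) for d in df["date"]]

    out: list[PeriodSummary] = []
    for (pid, per), grp in df.groupby(["person_id", "period"], sort=True):
        start, end = period_bounds(per)
        n_days_period = (end - start).days + 1
        coverage = grp["date"].nunique() / n_days_period
        stats: dict[str, tuple[float, float, int]] = {}
        for var in DAILY_VARIABLES:
            col = grp[var].dropna()
            if col.empty:
                continue
            stats[var] = (float(col.mean()), float(col.sum()), int(col.size))
        hr_max = grp["heartrate_max"].dropna()
        if not hr_max.empty:
            stats["heartrate_max_observed"] = (
                float(hr_max.max()),
                float(hr_max.max()),
                int(hr_max.size),
            )
        hr_rest = grp["heartrate_resting"].dropna()
        if not hr_rest.empty:
            stats["heartrate_resting_min"] = (
                float(hr_rest.min()),
                float(hr_rest.min()),
                int(hr_rest.size),
            )
        missing = coverage < min_coverage
        out.append(
            PeriodSummary(
                person_id=pid,
                period=per,
                period_kind=period_kind,
                coverage=coverage,
                missing=missing,
                stats=stats if not missing else {},
            )
        )
    out.sort(key=lambda s: (s.person_id, period_bounds(s.period)[0]))
    return out


def summaries_to_frame(summaries: Sequence[PeriodSummary]) -> pd.DataFrame:
    """Long-format export: person_id, period, variable, mean, total,
    n_days, coverage."""
    rows = []
    for s in summaries:
        if not s.stats:
            rows.append(
                {
                    "person_id": s.person_id,
                    "period": s.period,
                    "variable": None,
                    "mean": None,
                    "total": None,
                    "n_days": 0,
                    "coverage": s.coverage,
                }
            )
        for var, (mean, total, n) in s.stats.items():
            rows.append(
                {
                    "person_id": s.person_id,
                    "period": s.period,
                    "variable": var,
                    "mean": mean,
                    "total": total,
                    "n_days": n,
                    "coverage": s.coverage,
                }
            )
    return pd.DataFrame(
        rows, columns=["person_id", "period", "variable", "mean", "total", "n_days", "coverage"]
    )


def write_summaries(summaries: Sequence[PeriodSummary], path: str | Path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False)


@dataclass(frozen=True)
class StandardScore:
    """A measurement expressed in spread units from its norm-group centre."""

    variable: str
    value: float | None  # None marks an undefined score (zero spread)
    norm_group: str
    n: int

    @property
    def defined(self) -> bool:
        return self.value is not None and math.isfinite(self.value)


def standard_score(
    value: float,
    stratum_values: Sequence[float],
    center: Literal["mean", "median", "geometric_mean"] = "mean",
    spread: Literal["sd", "se"] = "sd",
    variable: str = "",
    norm_group: str = "sample",
) -> StandardScore:
    """Standard score of ``value`` against a norm stratum.

    ``z = (value - centre) / spread`` with a selectable centre (mean,
    median or geometric mean) and spread (sample standard deviation or
    standard error).  A stratum with zero spread yields an undefined
    score rather than an exception.
    """
    xs = [float(v) for v in stratum_values]
    if len(xs) < 2:
        raise ValueError("stratum needs at least 2 values")
    if center == "mean":
        c = statistics.fmean(xs)
    elif center == "median":
        c = statistics.median(xs)
    elif center == "geometric_mean":
        if any(v <= 0 for v in xs):
            raise ValueError("geometric mean needs positive stratum values")
        c = statistics.geometric_mean(xs)
    else:
        raise ValueError(f"unknown center {center!r}")
    sd = statistics.stdev(xs)
    s = sd if spread == "sd" else sd / math.sqrt(len(xs))
    if spread not in ("sd", "se"):
        raise ValueError(f"unknown spread {spread!r}")
    if s == 0:
        return StandardScore(variable, None, norm_group, len(xs))
    return StandardScore(variable, (value - c) / s, norm_group, len(xs))


def linear_aggregate(
    scores: Sequence[StandardScore], weights: dict[str, float] | None = None
) -> float | None:
    """Weighted arithmetic mean of defined standard scores (weights are
    renormalised to sum 1; default equal weights).  Returns None for
    empty input."""
    defined = [s for s in scores if s.defined]
    if not defined:
        return None
    if weights is None:
        w = np.ones(len(defined))
    else:
        try:
            w = np.array([float(weights[s.variable]) for s in defined])
        except KeyError as exc:
            raise ValueError(f"no weight for variable {exc}") from exc
    if w.sum() <= 0:
        raise ValueError("weights must sum to a positive value")
    z = np.array([s.value for s in defined])
    return float(np.dot(w, z) / w.sum())
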