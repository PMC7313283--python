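"""Correlation validation of the composite against self-report scores.

Each questionnaire response is paired with the respondent's composite
value for the nearest scored period (or the same calendar month), and
the paired sample is summarised by a Pearson (optionally Spearman)
correlation with a two-sided p-value.  Repeated responses by one person
form independent pairs, matching how respondents with two or three
questionnaire fillings enter the scatter.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd
from scipy import stats as _sps

from .aggregation import period_bounds
from .composite import CompositePoint, _points_frame
from .questionnaires import Eq5Response, EssResponse, score_eq5, score_ess

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationPair",
    "CorrelationResult",
    "pair_responses",
    "correlate",
    "scatter_export",
    "write_report",
]

#: Maximum distance between a response and the matched period mid-date.
NEAREST_HORIZON_DAYS = 45


@dataclass(frozen=True)
class ValidationPair:
    person_id: str
    questionnaire_score: float
    wb_ph: float
    window: str  # e.g. "same_month:2019-03" or "nearest_period:2019-W10"


@dataclass(frozen=True)
class CorrelationResult:
    r: float | None
    p_value: float | None
    n: int
    method: str = "pearson"

    @property
    def defined(self) -> bool:
        return self.r is not None


def _response_score(r: EssResponse | Eq5Response) -> float:
    return float(score_ess(r)) if isinstance(r, EssResponse) else score_eq5(r)


def _composites_frame(
    composites: Sequence[CompositePoint] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(composites, pd.DataFrame):
        df = composites[["person_id", "period", "WB_ph"]].copy()
    else:
        df = _points_frame(list(composites))[["person_id", "period", "WB_ph"]]
    mids = []
    for per in df["period"]:
        start, end = period_bounds(per)
        mids.append(start + (end - start) / 2)
    df["mid"] = mids
    return df


def pair_responses(
    responses: Sequence[EssResponse | Eq5Response],
    composites: Sequence[CompositePoint] | pd.DataFrame,
    window_policy: Literal["nearest_period", "same_month"] = "nearest_period",
    horizon_days: int = NEAREST_HORIZON_DAYS,
) -> list[ValidationPair]:
    """Match each response to its person's composite period.

    ``nearest_period`` picks the period whose mid-date is closest to the
    response timestamp within ``horizon_days``; ``same_month`` requires
    a monthly composite labelled with the response's calendar month.
    Unmatched responses are dropped with a logged count.
    """
    comp = _composites_frame(composites)
    pairs: list[ValidationPair] = []
    dropped = 0
    for r in responses:
        mine = comp[comp["person_id"] == r.person_id]
        if mine.empty:
            dropped += 1
            continue
        if window_policy == "same_month":
            label = f"{r.timestamp.year}-{r.timestamp.month:02d}"
            hit = mine[mine["period"] == label]
            if hit.empty:
                dropped += 1
                continue
            row = hit.iloc[0]
        elif window_policy == "nearest_period":
            deltas = (mine["mid"] - r.timestamp.date()).abs()
            k = deltas.idxmin()
            if deltas[k] > _dt.timedelta(days=horizon_days):
                dropped += 1
                continue
            row = mine.loc[k]
        else:
            raise ValueError(f"unknown window policy {window_policy!r}")
        pairs.append(
            ValidationPair(
                person_id=r.person_id,
                questionnaire_score=_response_score(r),
                wb_ph=float(row["WB_ph"]),
                window=f"{window_policy}:{row['period']}",
            )
        )
    if dropped:
        logger.warning("%d responses had no composite within the horizon", dropped)
    return pairs


def correlate(
    pairs: Sequence[ValidationPair],
    method: Literal["pearson", "spearman"] = "pearson",
) -> CorrelationResult:
    """Correlation between questionnaire scores and composite values.

    Pearson r with a two-sided t-test p-value (n - 2 degrees of
    freedom); Spearman available as an option.  Fewer than 3 pairs or a
    degenerate (zero-variance) margin yields an undefined result marker
    rather than an exception.
    """
    n = len(pairs)
    if n < 3:
        return CorrelationResult(None, None, n, method)
    x = [p.questionnaire_score for p in pairs]
    y = [p.wb_ph for p in pairs]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return CorrelationResult(None, None, n, method)
    if method == "pearson":
        res = _sps.pearsonr(x, y)
    elif method == "spearman":
        res = _sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(float(res.statistic), float(res.pvalue), n, method)


def pairs_to_frame(pairs: Sequence[ValidationPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "questionnaire_score": p.questionnaire_score,
                "WB_ph": p.wb_ph,
                "window": p.window,
            }
            for p in pairs
        ],
        columns=["person_id", "questionnaire_score", "WB_ph", "window"],
    )


def scatter_export(
    pairs: Sequence[ValidationPair],
    out_dir: str | Path,
    instrument: str = "questionnaire",
) -> tuple[Path, Path] | None:
    """Write the pair table (CSV) and a scatter plot (PNG) of composite
    value versus cumulative questionnaire score.  Empty input is a no-op
    with a warning."""
    if not pairs:
        logger.warning("no pairs to export")
        return None
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"pairs_{instrument}.csv"
    png_path = out_dir / f"scatter_{instrument}.png"
    pairs_to_frame(pairs).to_csv(csv_path, index=False)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(
        [p.questionnaire_score for p in pairs],
        [p.wb_ph for p in pairs],
        alpha=0.6,
        edgecolor="none",
    )
    ax.set_xlabel(f"cumulative {instrument.upper()} score")
    ax.set_ylabel("composite well-being WB_ph")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
    return csv_path, png_path


def write_report(
    result: CorrelationResult,
    instrument: str,
    policy: str,
    path: str | Path,
) -> None:
    """Validation report JSON: instrument, n, r, p_value, policy."""
    with open(path, "w") as fh:
        json.dump(
            {
                "instrument": instrument,
                "n": result.n,
                "r": result.r,
                "p_value": result.p_value,
                "method": result.method,
                "policy": policy,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
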