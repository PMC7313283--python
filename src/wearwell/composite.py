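"""The composite physical well-being indicator.

The four domain indices are combined with a weighted geometric mean

    WB_ph = (I_w**Wt_w * I_p**Wt_p * I_s**Wt_s * I_c**Wt_c) ** (1/r)

with the root ``r`` either fixed at 4 (the literal published form) or
equal to the weight sum (the normalised weighted power mean).  The
default weights (0.9, 1.0, 1.05, 1.05) sum to 4, so the two modes
coincide there.  The geometric mean is used for its sensitivity to a low
value in any single domain and because the indices live on different
scales (1-5, 1-4, 1-2, 1-7) without requiring normalisation.

Composition is all-or-nothing: a period missing any domain index yields
a missing composite point, never a partial product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd
import yaml

from .aggregation import period_bounds
from .scores import DomainIndices

__all__ = [
    "CompositeWeights",
    "CompositePoint",
    "DEFAULT_WEIGHTS",
    "compose",
    "composite_series",
    "write_composites",
    "read_composites",
    "load_weights",
]

RootMode = Literal["fixed_4", "weight_sum"]


@dataclass(frozen=True)
class CompositeWeights:
    """Positive weight factors for the four domain indices.

    The defaults down-weight walking (0.9) against the known step-count
    overestimation of common wrist devices and up-weight sleep and
    cardio fitness (1.05) for their disease-risk relevance.
    """

    walking: float = 0.9
    activity: float = 1.0
    sleep: float = 1.05
    cardio: float = 1.05

    def __post_init__(self) -> None:
        if min(self.walking, self.activity, self.sleep, self.cardio) <= 0:
            raise ValueError("all weights must be > 0")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.walking, self.activity, self.sleep, self.cardio)

    @property
    def total(self) -> float:
        return sum(self.as_tuple())


DEFAULT_WEIGHTS = CompositeWeights()


@dataclass(frozen=True)
class CompositePoint:
    """One period's composite well-being value with its provenance."""

    person_id: str
    period: str
    wb_ph: float
    indices: DomainIndices
    weights: CompositeWeights
    root_mode: str


def compose(
    idx: DomainIndices,
    weights: CompositeWeights = DEFAULT_WEIGHTS,
    root_mode: RootMode = "fixed_4",
) -> CompositePoint | None:
    """Weighted geometric-mean composite of the four domain indices.

    Returns None (a missing point) when any index is absent.  Indices
    must be positive — the scoring scales all start at 1.
    """
    if not idx.complete:
        return None
    values = idx.as_tuple()
    if min(values) <= 0:
        raise ValueError(f"domain indices must be positive, got {values}")
    root = 4.0 if root_mode == "fixed_4" else weights.total
    if root_mode not in ("fixed_4", "weight_sum"):
        raise ValueError(f"unknown root_mode {root_mode!r}")
    log_sum = sum(w * math.log(v) for w, v in zip(weights.as_tuple(), values))
    return CompositePoint(
        person_id=idx.person_id,
        period=idx.period,
        wb_ph=math.exp(log_sum / root),
        indices=idx,
        weights=weights,
        root_mode=root_mode,
    )


def composite_series(
    indices_by_period: Iterable[DomainIndices],
    weights: CompositeWeights = DEFAULT_WEIGHTS,
    root_mode: RootMode = "fixed_4",
) -> list[CompositePoint]:
    """One composite point per fully-scored period, chronologically
    ordered per person; incomplete periods are dropped (gaps preserved
    as absent labels)."""
    indices = list(indices_by_period)
    seen: set[tuple[str, str]] = set()
    for ix in indices:
        key = (ix.person_id, ix.period)
        if key in seen:
            raise ValueError(f"duplicate period {key}")
        seen.add(key)
    points = [p for ix in indices if (p := compose(ix, weights, root_mode))]
    points.sort(key=lambda p: (p.person_id, period_bounds(p.period)[0]))
    return points


def _points_frame(points: Sequence[CompositePoint]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "person_id": p.person_id,
                "period": p.period,
                "I_w": p.indices.walking,
                "I_p": p.indices.activity,
                "I_s": p.indices.sleep,
                "I_c": p.indices.cardio,
                "WB_ph": p.wb_ph,
                "Wt_w": p.weights.walking,
                "Wt_p": p.weights.activity,
                "Wt_s": p.weights.sleep,
                "Wt_c": p.weights.cardio,
                "root_mode": p.root_mode,
            }
            for p in points
        ],
        columns=[
            "person_id", "period", "I_w", "I_p", "I_s", "I_c",
            "WB_ph", "Wt_w", "Wt_p", "Wt_s", "Wt_c", "root_mode",
        ],
    )


def write_composites(points: Sequence[CompositePoint], path: str | Path) -> None:
    """Export composite points as CSV with indices, value, weights and
    root mode."""
    _points_frame(points).to_csv(path, index=False, float_format="%.10g")


def read_composites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str})
    required = {"person_id", "period", "WB_ph"}
    if not required.issubset(df.columns):
        raise ValueError(f"composites CSV missing columns {required - set(df.columns)}")
    return df


def load_weights(path: str | Path) -> CompositeWeights:
    """Read a weights config (YAML/JSON mapping with keys walking,
    activity, sleep, cardio)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("weights config must be a mapping")
    unknown = set(raw) - {"walking", "activity", "sleep", "cardio"}
    if unknown:
        raise ValueError(f"unknown weight keys {sorted(unknown)}")
    return CompositeWeights(**{k: float(v) for k, v in raw.items()})
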