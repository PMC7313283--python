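"""Scoring of the two self-report well-being instruments.

* ESS — a 15-statement well-being questionnaire rated on a 5-degree
  Likert scale (Strongly agree = 4 .. Strongly disagree = 0); the
  cumulative score is the plain item sum, 0 (worst) to 60 (optimum).
* EQ5 — a five-dimension health-status instrument (mobility, self-care,
  usual activities, pain/discomfort, anxiety/depression) self-rated
  1 (worst) to 5 (best), plus a 0-100 health-state assessment (hsa)
  mapped onto 1-5 by ``1 + 4 * hsa / 100``; the cumulative score is the
  dimension sum plus the mapped hsa, ranging 6 to 30.

Note the dimension polarity: here 5 is best, the reverse of the
conventional EQ-5D level coding where 5 is the worst problem level.
``read_responses`` accepts ``eq5_polarity="standard"`` to invert
conventionally coded files on ingestion (rating -> 6 - rating).
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

__all__ = [
    "EssResponse",
    "Eq5Response",
    "score_ess",
    "score_eq5",
    "map_hsa",
    "read_responses",
    "write_responses",
]

ESS_ITEMS = 15
EQ5_DIMS = 5


@dataclass(frozen=True)
class EssResponse:
    person_id: str
    timestamp: _dt.datetime
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.items) != ESS_ITEMS:
            raise ValueError(f"ESS needs exactly {ESS_ITEMS} items, got {len(self.items)}")
        if any(not (isinstance(i, int) and 0 <= i <= 4) for i in self.items):
            raise ValueError("ESS item ratings must be integers in 0..4")


@dataclass(frozen=True)
class Eq5Response:
    person_id: str
    timestamp: _dt.datetime
    dimensions: tuple[int, ...]  # 1 = worst .. 5 = best
    hsa: float  # health-state assessment, 0-100

    def __post_init__(self) -> None:
        if len(self.dimensions) != EQ5_DIMS:
            raise ValueError(f"EQ5 needs exactly {EQ5_DIMS} dimensions")
        if any(not (isinstance(d, int) and 1 <= d <= 5) for d in self.dimensions):
            raise ValueError("EQ5 dimension ratings must be integers in 1..5")
        if not 0 <= self.hsa <= 100:
            raise ValueError("hsa must be in [0, 100]")


def score_ess(response: EssResponse) -> int:
    """Cumulative ESS score: the sum of the 15 item ratings (0-60)."""
    return sum(response.items)


def map_hsa(hsa: float) -> float:
    """Map the 0-100 health-state assessment onto the 1-5 dimension
    scale: ``1 + 4 * hsa / 100``."""
    if not 0 <= hsa <= 100:
        raise ValueError("hsa must be in [0, 100]")
    return 1 + 4 * hsa / 100


def score_eq5(response: Eq5Response) -> float:
    """Cumulative EQ5 score: dimension sum plus mapped hsa (6-30).
    The mapped hsa is kept fractional — no rounding before summation."""
    return sum(response.dimensions) + map_hsa(response.hsa)


# ---------------------------------------------------------------------------
# CSV I/O: person_id, timestamp, instrument, then q1..q15 (ess) or
# d1..d5,hsa (eq5).  A file may mix instruments; the reader filters.

def read_responses(
    path: str | Path,
    instrument: Literal["ess", "eq5"],
    eq5_polarity: Literal["best_high", "standard"] = "best_high",
) -> list[EssResponse] | list[Eq5Response]:
    """Read questionnaire responses of one instrument from CSV.

    ``eq5_polarity="standard"`` inverts conventionally coded EQ-5D
    levels (1 = no problems) into the best-high coding used here.
    """
    df = pd.read_csv(path, dtype={"person_id": str})
    if "instrument" in df.columns:
        df = df[df["instrument"] == instrument]
    out: list = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        ts = _dt.datetime.fromisoformat(str(getattr(row, "timestamp")))
        try:
            if instrument == "ess":
                items = tuple(int(getattr(row, f"q{k}")) for k in range(1, ESS_ITEMS + 1))
                out.append(EssResponse(row.person_id, ts, items))
            else:
                dims = tuple(int(getattr(row, f"d{k}")) for k in range(1, EQ5_DIMS + 1))
                if eq5_polarity == "standard":
                    dims = tuple(6 - d for d in dims)
                out.append(Eq5Response(row.person_id, ts, dims, float(row.hsa)))
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def write_responses(
    responses: Sequence[EssResponse | Eq5Response], path: str | Path
) -> None:
    rows = []
    for r in responses:
        base = {"person_id": r.person_id, "timestamp": r.timestamp.isoformat()}
        if isinstance(r, EssResponse):
            base["instrument"] = "ess"
            base.update({f"q{k}": v for k, v in enumerate(r.items, start=1)})
        else:
            base["instrument"] = "eq5"
            base.update({f"d{k}": v for k, v in enumerate(r.dimensions, start=1)})
            base["hsa"] = r.hsa
        rows.append(base)
    cols = ["person_id", "timestamp", "instrument"]
    cols += [f"q{k}" for k in range(1, ESS_ITEMS + 1)]
    cols += [f"d{k}" for k in range(1, EQ5_DIMS + 1)] + ["hsa"]
    df = pd.DataFrame(rows)
    df = df.reindex(columns=[c for c in cols if c in df.columns])
    df.to_csv(path, index=False)
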