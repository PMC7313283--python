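"""Independent brute-force oracles for the threshold scorers.

Each oracle is a direct interval-membership scan over the published band
lists, written separately from the package's cascaded-threshold
implementations so the two can disagree.
"""

from __future__ import annotations

import math

# (lower inclusive, upper exclusive, score) — walking bands, steps/day
WALKING_BANDS = [
    (12500, math.inf, 5),  # highly active
    (10000, 12500, 4),     # active
    (7500, 10000, 3),      # somewhat active
    (5000, 7500, 2),       # lowly active
    (0, 5000, 1),          # sedentary
]

# weekly moderate-equivalent minutes (vigorous counts double)
ACTIVITY_BANDS = [
    (150, math.inf, 4),  # meets aerobic guidelines
    (60, 150, 3),        # certain activity
    (30, 60, 2),         # low activity
    (0, 30, 1),          # inactive
]

# age range (years, upper exclusive; None = open) -> recommended band and
# the mildly-risky envelope, straight from the published sleep table with
# its gaps closed towards the recommended range
SLEEP_TABLE = [
    ((0, 0.33), (14, 17), (11, 19)),    # newborns
    ((0.33, 1), (12, 15), (10, 18)),    # infants
    ((1, 3), (11, 14), (9, 16)),        # toddlers
    ((3, 6), (10, 13), (8, 14)),        # preschoolers
    ((6, 14), (9, 11), (7, 12)),        # school-aged children
    ((14, 18), (8, 10), (7, 11)),       # teenagers
    ((18, 26), (7, 9), (6, 11)),        # young adults
    ((26, 65), (7, 9), (6, 10)),        # adults
    ((65, None), (7, 8), (5, 9)),       # older adults
]


def walking_oracle(steps: float) -> int:
    for lo, hi, score in WALKING_BANDS:
        if lo <= steps < hi:
            return score
    raise AssertionError(steps)


def activity_oracle(moderate_min: float, vigorous_min: float) -> int:
    m = moderate_min + 2 * vigorous_min
    for lo, hi, score in ACTIVITY_BANDS:
        if lo <= m < hi:
            return score
    raise AssertionError(m)


def sleep_oracle(age: float, hours: float) -> float:
    for (a_lo, a_hi), (r_lo, r_hi), (e_lo, e_hi) in SLEEP_TABLE:
        if age >= a_lo and (a_hi is None or age < a_hi):
            if r_lo <= hours <= r_hi:
                return 2.0
            if e_lo <= hours <= e_hi:
                return 1.75
            return 1.0
    raise AssertionError(age)


def vo2max_oracle(value: float, cuts: list[float]) -> int:
    """Interval scan over the seven categories implied by six cut-points:
    category k+1 starts at cut k (closed); only values strictly above the
    sixth cut are elite."""
    intervals = (
        [(-math.inf, cuts[0], 1)]
        + [(cuts[i], cuts[i + 1], i + 2) for i in range(4)]
        + [(cuts[4], cuts[5], 6)]
    )
    if value > cuts[5]:
        return 7
    for lo, hi, score in intervals:
        if lo <= value < hi or (score == 6 and value == cuts[5]):
            return score
    raise AssertionError(value)


def pearson_oracle(xs: list[float], ys: list[float]) -> float:
    """Textbook covariance / (sd_x * sd_y)."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    cov = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    vx = sum((x - mx) ** 2 for x in xs)
    vy = sum((y - my) ** 2 for y in ys)
    return cov / math.sqrt(vx * vy)
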