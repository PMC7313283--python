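# Reference norm tables used by the domain scorers.
#
# sleep: US National Sleep Foundation age-stratified sleep-duration
#   recommendations.  Each category gives its age range in years
#   (age_max exclusive; the last category is open-ended) and two bands
#   in hours: `recommended` [lo, hi] (closed) and `appropriate`
#   [lo, hi], the outer envelope of the "may be appropriate" durations
#   on both sides of the recommended range.  Durations inside the
#   appropriate envelope but outside the recommended band score as
#   mildly risky; durations outside the envelope are not recommended.
#   Published gaps between the printed bands (e.g. adults: appropriate
#   6 h, recommended 7-9 h) are closed by continuity, with bounds
#   closed on the side nearer the recommended range.
#
# vo2max: non-exercise cardiorespiratory fitness norms after
#   Shvartz & Reibold's aerobic fitness tables, as six ascending
#   cut-points (mL/(kg*min)) separating the seven categories
#   1 very low .. 7 elite.  A value at or above cut-point k (k = 1..5)
#   reaches at least score k+1; the sixth cut-point is the inclusive
#   upper bound of category 6, so only values strictly above it score
#   7.  Brackets below 18 years are not packaged; ages outside the
#   listed brackets clamp to the nearest one.

sleep:
  - {name: newborns,     age_min: 0,     age_max: 0.33,  recommended: [14, 17], appropriate: [11, 19]}
  - {name: infants,      age_min: 0.33,  age_max: 1,     recommended: [12, 15], appropriate: [10, 18]}
  - {name: toddlers,     age_min: 1,     age_max: 3,     recommended: [11, 14], appropriate: [9, 16]}
  - {name: preschoolers, age_min: 3,     age_max: 6,     recommended: [10, 13], appropriate: [8, 14]}
  - {name: school_age,   age_min: 6,     age_max: 14,    recommended: [9, 11],  appropriate: [7, 12]}
  - {name: teenagers,    age_min: 14,    age_max: 18,    recommended: [8, 10],  appropriate: [7, 11]}
  - {name: young_adults, age_min: 18,    age_max: 26,    recommended: [7, 9],   appropriate: [6, 11]}
  - {name: adults,       age_min: 26,    age_max: 65,    recommended: [7, 9],   appropriate: [6, 10]}
  - {name: older_adults, age_min: 65,    age_max: null,  recommended: [7, 8],   appropriate: [5, 9]}

vo2max:
  male:
    - {age_min: 18, age_max: 25, cuts: [30, 37, 42, 47, 52, 60]}
    - {age_min: 26, age_max: 35, cuts: [30, 35, 40, 43, 49, 56]}
    - {age_min: 36, age_max: 45, cuts: [26, 31, 35, 39, 45, 51]}
    - {age_min: 46, age_max: 55, cuts: [25, 29, 33, 36, 41, 45]}
    - {age_min: 56, age_max: 65, cuts: [22, 26, 30, 32, 36, 41]}
    - {age_min: 66, age_max: 75, cuts: [20, 22, 26, 29, 33, 37]}
  female:
    - {age_min: 18, age_max: 25, cuts: [28, 33, 37, 42, 47, 56]}
    - {age_min: 26, age_max: 35, cuts: [26, 31, 35, 40, 45, 52]}
    - {age_min: 36, age_max: 45, cuts: [22, 27, 30, 34, 41, 45]}
    - {age_min: 46, age_max: 55, cuts: [20, 23, 27, 31, 37, 40]}
    - {age_min: 56, age_max: 65, cuts: [18, 21, 23, 28, 32, 37]}
    - {age_min: 66, age_max: 75, cuts: [17, 19, 21, 24, 31, 32]}
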