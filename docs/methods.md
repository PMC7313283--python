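# Methods

`wearwell` implements a baseline, rule-based model of physical
well-being computed from consumer wearable-device time series, together
with the questionnaire scoring and correlation validation used to assess
it, and a synthetic cohort generator that makes the whole pipeline
runnable without any real data.

## The model

Daily measurements (one row per person-day: steps, activity seconds by
intensity, sleep-phase seconds, heart-rate summaries) are aggregated
into per-person calendar periods — ISO weeks (Monday–Sunday) or calendar
months — and each period is scored on four domains:

**Walking (I_w, 1–5).** Mean daily steps banded by the common
healthy-adult classification: ≥ 12,500 highly active (5);
10,000–12,499 active (4); 7,500–9,999 somewhat active (3); 5,000–7,499
lowly active (2); < 5,000 sedentary (1).

**Physical activity / exercise (I_p, 1–4).** Weekly moderate-equivalent
minutes `m = moderate + 2 × vigorous`, banded by the aerobic activity
guidelines: m ≥ 150 meets guidelines (4); 60–149 certain activity (3);
30–59 low activity (2); < 30 inactive (1).  The factor 2 encodes the
guidelines' paired thresholds (150 moderate ≡ 75 vigorous, 60 ≡ 30,
30 ≡ 15); the published category lists name the 60–149 band both
"asserted activity" and "certain activity" — we treat them as one
category with score 3.

**Sleep duration (I_s ∈ {1, 1.75, 2}).** Mean daily total sleep time in
hours against the US National Sleep Foundation age-stratified bands:
2 in the recommended range, 1.75 in the "may be appropriate" range
(relabelled *mildly risky* to reflect the dose–response risk evidence
for both under- and over-sleep), 1 outside it.  The asymmetric 1.75
reflects that the mildly-risky band carries much less risk than the
not-recommended one.  The published table has gaps (e.g. adults:
appropriate "6 h", recommended "7 to 9 h"); we close them by continuity
so every duration in (0, 24] maps to a band, with boundaries closed on
the side nearer the recommended range (adults: appropriate
[6, 7) ∪ (9, 10]).  Total `sleep_time` is used, not `sleep_asleep_time`;
sleep-phase quality modelling is out of scope.

**Cardio-respiratory fitness (I_c, 1–7).** The non-exercise VO2max
estimate `VO2max ≈ (hr_max / hr_rest) × 15.3` mL/(kg·min), categorised
1 *very low* … 7 *elite* against gender- and age-stratified aerobic
fitness norms (after Shvartz & Reibold).  `hr_max` is the
device-observed maximum over the scoring period when at least one
reading exists, else the crude `220 − age`; `hr_rest` is the period
mean of daily resting heart rate (a period-minimum option exists for
users who prefer the conservative convention).  The norm table ships as
an editable YAML reference file covering ages 18–75 in six brackets per
gender; ages outside clamp to the nearest bracket, and an unspecified
gender scores against the mean of the male and female cut-points rather
than being refused.

All band thresholds are closed on the lower bound of the higher band
("12,500 or more", "at least 150"), making every scorer a total,
monotone non-decreasing step function of its input (sleep is instead
unimodal around the recommended band).  In the fitness table the
topmost cut-point is the inclusive upper bound of category 6, matching
the "X to Y" / "more than Y" phrasing of published norm rows.

## The composite indicator

The four indices combine into the composite physical well-being value

    WB_ph = (I_w^Wt_w · I_p^Wt_p · I_s^Wt_s · I_c^Wt_c)^(1/4)

a weighted geometric mean with default weights Wt = (0.9, 1.0, 1.05,
1.05) for walking, activity, sleep and cardio respectively — walking is
down-weighted against the known step over-counting of wrist trackers,
sleep and fitness up-weighted for their disease-risk relevance.  The
geometric mean is chosen for its sensitivity to a low value in any one
domain and because the indices live on different scales without
normalisation.  Two root conventions are implemented: the literal fixed
fourth root (default) and the normalised `1/ΣWt` weighted power mean;
the defaults sum to 4, so they coincide there.  With `weight_sum` the
power-mean bound min ≤ WB_ph ≤ max holds for any weights.  Weights are
configuration (YAML), not code.

Composition is all-or-nothing: a period missing any of the four indices
yields a missing composite, because silently dropping a factor whose low
value is exactly what the geometric mean is meant to expose would bias
the composite upward.  With the index ranges above, WB_ph lies roughly
in [1, 4.5] under default weights (a derived consequence, not an
asserted property).

Aggregation details: coverage is the fraction of the period's calendar
days with any data; periods under the minimum coverage (defaults 4/7
weekly, 15/31 monthly — the model itself is silent on missing-day
handling) are flagged missing.  Weekly activity minutes are computed as
`mean daily seconds × 7 / 60`, which equals the summed week when
coverage is full and remains unbiased when days are missing.  Absent
cells are absent, never zero; however, within the activity domain a
period reporting one intensity but not the other treats the unreported
intensity as zero minutes, since trackers emit no row for intensities
not reached — absence of both leaves the domain unscored.  The
complementary data-driven primitives — standard scores against a norm
stratum with selectable centre (mean / median / geometric mean) and
spread (sd / se), and weighted linear aggregation of such scores — are
provided as the building blocks for indicator synthesis over relative
changes; the default centre stays the mean, with the median available
where outlier-resistance matters.

## Questionnaires and validation

ESS: 15 statements rated 0–4, summed to 0–60.  EQ5: five dimensions
rated 1 (worst) to 5 (best) plus a 0–100 health-state assessment mapped
by `1 + 4·hsa/100` and added, giving 6–30; the mapped value is kept
fractional.  Note the dimension polarity is best-high — the reverse of
conventional EQ-5D level coding — so the reader accepts a polarity flag
that inverts standard-coded files (`rating → 6 − rating`).

Validation pairs each response with the person's composite for the
nearest scored period (mid-date within ±45 days; a same-calendar-month
policy is available) and reports a Pearson correlation with a two-sided
t-distribution p-value on n − 2 degrees of freedom (Spearman optional).
Repeated responses by one person enter as independent pairs — the
convention matching scatter plots that count each filling separately;
per-person averaging would be the natural alternative and is not
implemented.  Fewer than three pairs or a degenerate margin yields an
explicit undefined-result marker.

## The synthetic cohort

Each simulated person carries a latent well-being level L ~ N(0.55,
0.20) clipped to [0, 1].  Monotone links drive the streams: daily steps
are negative binomial (dispersion 12) with mean 1,500 + 13,500·L;
moderate/vigorous activity seconds are zero-inflated gamma draws whose
weekly moderate-equivalent minutes scale as ≈ 380·L^2.2, spanning all
four guideline bands over the latent range; sleep hours are normal
around 5.3 + 3.4·L (sd 0.5, truncated to [2.5, 13]), putting high-L
persons in the recommended band and low-L persons below it; resting
heart rate is normal around 78 − 24·L; device maximum heart rate is
emitted on about half of days around 220 − age − 8.  Days are dropped
independently at a 10 % missingness rate.  Questionnaire items
discretise `clip(L + N(0, σ), 0, 1)` onto their rating scales with
σ = 0.15 by default; each person fills the questionnaires one to three
times.  Per-domain link strengths in [0, 1] interpolate each stream
toward cohort-average behaviour, severing the latent signal at 0.  All
randomness flows from a single seeded NumPy generator, so a cohort is
byte-reproducible from its config.

What the generator does *not* emulate: circadian intra-day structure,
seasonality, device-specific noise beyond a single multiplicative step
over-counting factor, and any correlation between age/gender and the
latent level.  Passing recovery tests therefore demonstrates that the
pipeline is correct and sensitive under the model's own assumptions
(monotone latent links), not that the composite is valid on real
populations.

A separate hand-written golden fixture (four persons × eight ISO weeks
of constant behaviour) places each person in a known band per domain
— e.g. 13,000 steps/day → I_w = 5; 20 moderate min/week → I_p = 1; a
30-year-old at 6 h sleep → I_s = 1.75 — and anchors the byte-stability
and end-to-end contract tests.

## Numerical and design notes

- Heart-rate zones tile (0.5, 1.0]·hr_max with boundaries closed on the
  lower bound of the higher zone (85 % → peak, 70 % → cardio).
- Dates are ISO-8601 calendar days; intra-daily timestamps are
  timezone-naive local time at one-minute resolution.
- CSV is the interchange format throughout, with columns named exactly
  after the measured variables; empty cells mean "not measured".
- An inverted heart-rate ratio (hr_max < hr_rest) warns but still
  computes, since transient device artefacts should not void a period.
- Test problem sizes: recovery tests run 30–50 persons over 3–6 months,
  which is ample for the strong synthetic links; the questionnaire-noise
  trend is checked at σ ∈ {0.05, 0.3, 0.7}, levels far enough apart that
  the discretisation dithering near σ = 0 (a small amount of noise can
  *smooth* the coarse rating scales and nudge the correlation up) cannot
  mask the monotone degradation.

## Limitations

The domain thresholds are adult-population heuristics, not clinical
instruments; the fitness norms below age 18 are not packaged (ages
clamp); blood-pressure and calorie-based scoring, intra-day behaviour
models, and any learned (non-rule-based) scoring are out of scope.  The
composite's weights are defaults to be tuned against validation data,
and the correlation validation here runs only on synthetic cohorts.
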